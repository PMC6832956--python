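"""Generation of synthetic Raman spectra and class-structured datasets.

The signal model per spectrum is

    intensities = scatter * clean_signal + baseline + water_weight * water
                  + shot noise + cosmic spikes

where ``clean_signal`` is the profile's band sum, ``scatter`` is a
per-spectrum multiplicative factor (mean 1) emulating sampling-volume and
focus variation, the baseline is the profile's fluorescence polynomial, and
spikes are one-channel deltas 10-100x the local amplitude.  All components
are stored alongside the spectrum so that tests can close the loop exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidProfileError
from ..spectrum import DEFAULT_ACQUISITION, Spectrum, SpectralDataset
from .profiles import ClassProfile, water_reference


@dataclass
class SpectrumDesign:
    """Axis layout and stochastic settings for spectrum generation.

    Defaults: a 600-3100 cm^-1 axis with 1200 channels (covering both the
    fingerprint region 758-1800 cm^-1 and the CH-stretch band at 2851 cm^-1),
    150 spectra per class, 10% multiplicative scatter, additive noise with
    sd 0.02 on unit-amplitude bands, and on average 0.05 cosmic spikes per
    spectrum.
    """

    axis_min: float = 600.0
    axis_max: float = 3100.0
    n_channels: int = 1200
    n_per_class: int = 150
    scatter_sd: float = 0.1
    noise_sd: float = 0.02
    spike_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_min >= self.axis_max:
            raise ValueError("axis_min must be < axis_max")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if min(self.scatter_sd, self.noise_sd, self.spike_rate) < 0:
            raise ValueError("scatter_sd, noise_sd and spike_rate must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_min, self.axis_max, self.n_channels)


@dataclass
class GeneratedSpectrum:
    """A synthetic spectrum together with its ground-truth components."""

    spectrum: Spectrum
    signal: np.ndarray          # scatter * clean band sum
    baseline: np.ndarray        # fluorescence polynomial
    water: np.ndarray           # water_weight * water reference
    noise: np.ndarray
    scatter: float
    spike_channels: np.ndarray  # channel indices of inserted cosmic spikes
    spike_delta: np.ndarray     # full-length vector of added spike intensity

    def components_sum(self) -> np.ndarray:
        return self.signal + self.baseline + self.water + self.noise + self.spike_delta


def generate_spectrum(
    profile: ClassProfile,
    design: SpectrumDesign,
    rng: np.random.Generator,
    spectrum_id: str | None = None,
) -> GeneratedSpectrum:
    """Draw one spectrum from ``profile`` under ``design``.

    Deterministic in the state of ``rng``; callers wanting reproducibility
    pass ``np.random.default_rng(seed)``.
    """
    profile.validate(design.axis_min, design.axis_max)
    axis = design.axis()
    clean = profile.clean_signal(axis)
    scatter = float(max(1.0 + design.scatter_sd * rng.standard_normal(), 0.05))
    signal = scatter * clean
    baseline = profile.baseline(axis)
    water = profile.water_weight * water_reference(axis)
    noise = design.noise_sd * rng.standard_normal(axis.size) if design.noise_sd > 0 else np.zeros_like(axis)

    spike_delta = np.zeros_like(axis)
    n_spikes = rng.poisson(design.spike_rate) if design.spike_rate > 0 else 0
    spike_channels = np.sort(rng.choice(axis.size, size=min(n_spikes, axis.size), replace=False))
    local_scale = max(float(np.max(np.abs(signal + baseline + water))), 1.0)
    for ch in spike_channels:
        spike_delta[ch] = rng.uniform(10.0, 100.0) * local_scale

    intensities = signal + baseline + water + noise + spike_delta
    meta = dict(DEFAULT_ACQUISITION)
    meta.update(
        id=spectrum_id or profile.name,
        species=profile.name,
        genus=profile.genus,
        family=profile.family,
        growth_habit=profile.growth_habit,
    )
    return GeneratedSpectrum(
        spectrum=Spectrum(axis, intensities, meta),
        signal=signal,
        baseline=baseline,
        water=water,
        noise=noise,
        scatter=scatter,
        spike_channels=np.asarray(spike_channels, dtype=int),
        spike_delta=spike_delta,
    )


def generate_dataset(
    profiles: list[ClassProfile],
    design: SpectrumDesign,
    return_truth: bool = False,
) -> SpectralDataset | tuple[SpectralDataset, list[GeneratedSpectrum]]:
    """Generate ``design.n_per_class`` spectra per profile with a manifest.

    The manifest carries id, species, genus, family and growth_habit per row;
    row order is (profile order) x (replicate index).
    """
    if not profiles:
        raise InvalidProfileError("at least one class profile is required")
    rng = np.random.default_rng(design.seed)
    axis = design.axis()
    rows = []
    matrix = np.empty((len(profiles) * design.n_per_class, axis.size))
    truth: list[GeneratedSpectrum] = []
    i = 0
    for profile in profiles:
        for rep in range(design.n_per_class):
            sid = f"{profile.name.replace(' ', '_')}_{rep:04d}"
            gen = generate_spectrum(profile, design, rng, spectrum_id=sid)
            matrix[i] = gen.spectrum.intensities
            rows.append(
                {
                    "id": sid,
                    "species": profile.name,
                    "genus": profile.genus,
                    "family": profile.family,
                    "growth_habit": profile.growth_habit,
                }
            )
            if return_truth:
                truth.append(gen)
            i += 1
    dataset = SpectralDataset(axis, matrix, pd.DataFrame(rows))
    return (dataset, truth) if return_truth else dataset
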