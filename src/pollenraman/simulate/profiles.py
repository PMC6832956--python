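"""Spectral class profiles for the synthetic pollen taxonomy.

A :class:`ClassProfile` describes one pollen taxon's idealized Raman
signature: a set of Gaussian bands, a smooth fluorescence baseline (at most
quadratic), and a weight on a broad water background.  The default taxonomy
template mirrors the structure of a 37-taxon screening panel spanning four
growth habits (grass, herb, shrub, tree), 18 families and 36 genera, with
band positions taken from the regions that discriminate pollen biochemistry:
nucleic-acid ring breathing (783 cm^-1), phenylalanine (1004 cm^-1), lipid
CH2 modes (1065, 1304, 1441, 1750, 2851 cm^-1), sporopollenin aromatics
(1173, 1209, 1590, 1610, 1637 cm^-1) and amide I (1660 cm^-1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidProfileError

GROWTH_HABITS = ("grass", "herb", "shrub", "tree")

#: Band centers (cm^-1) used by the default profiles, with nominal widths.
RAMAN_BAND_POOL: tuple[tuple[float, float], ...] = (
    (783.0, 9.0),
    (1004.0, 7.0),
    (1065.0, 10.0),
    (1173.0, 10.0),
    (1209.0, 10.0),
    (1263.0, 12.0),
    (1304.0, 11.0),
    (1441.0, 13.0),
    (1590.0, 10.0),
    (1610.0, 9.0),
    (1637.0, 9.0),
    (1660.0, 14.0),
    (1750.0, 12.0),
    (2851.0, 16.0),
)

# (growth habit, family, genus, species) rows of the default screening panel:
# 16 grasses, 5 herbs, 5 shrubs, 11 trees; the two Artemisia species share a
# genus, so the panel has 37 species but 36 genera and 18 families.
TAXONOMY_TABLE: tuple[tuple[str, str, str, str], ...] = (
    ("grass", "Poaceae", "Festuca", "Festuca sp."),
    ("grass", "Poaceae", "Arrhenatherum", "Arrhenatherum sp."),
    ("grass", "Poaceae", "Holcus", "Holcus sp."),
    ("grass", "Poaceae", "Phleum", "Phleum sp."),
    ("grass", "Poaceae", "Lolium", "Lolium sp."),
    ("grass", "Poaceae", "Molinia", "Molinia sp."),
    ("grass", "Poaceae", "Elymus", "Elymus sp."),
    ("grass", "Poaceae", "Calamagrostis", "Calamagrostis sp."),
    ("grass", "Poaceae", "Poa", "Poa sp."),
    ("grass", "Poaceae", "Secale", "Secale sp."),
    ("grass", "Poaceae", "Phragmites", "Phragmites sp."),
    ("grass", "Poaceae", "Deschampsia", "Deschampsia sp."),
    ("grass", "Cyperaceae", "Scirpus", "Scirpus sp."),
    ("grass", "Poaceae", "Agrostis", "Agrostis sp."),
    ("grass", "Poaceae", "Bromus", "Bromus sp."),
    ("grass", "Poaceae", "Helictotrichon", "Helictotrichon sp."),
    ("herb", "Primulaceae", "Cyclamen", "Cyclamen sp."),
    ("herb", "Polygonaceae", "Rumex", "Rumex sp."),
    ("herb", "Amaranthaceae", "Amaranthus", "Amaranthus sp."),
    ("herb", "Papaveraceae", "Papaver", "Papaver sp."),
    ("herb", "Plantaginaceae", "Plantago", "Plantago sp."),
    ("shrub", "Asteraceae", "Artemisia", "Artemisia absinthium"),
    ("shrub", "Rosaceae", "Rosa", "Rosa sp."),
    ("shrub", "Asteraceae", "Ambrosia", "Ambrosia sp."),
    ("shrub", "Asteraceae", "Helianthus", "Helianthus sp."),
    ("shrub", "Asteraceae", "Artemisia", "Artemisia vulgaris"),
    ("tree", "Betulaceae", "Alnus", "Alnus sp."),
    ("tree", "Oleaceae", "Fraxinus", "Fraxinus sp."),
    ("tree", "Ranunculaceae", "Ranunculus", "Ranunculus sp."),
    ("tree", "Betulaceae", "Corylus", "Corylus sp."),
    ("tree", "Adoxaceae", "Sambucus", "Sambucus sp."),
    ("tree", "Pinaceae", "Larix", "Larix sp."),
    ("tree", "Salicaceae", "Populus", "Populus sp."),
    ("tree", "Platanaceae", "Platanus", "Platanus sp."),
    ("tree", "Fagaceae", "Fagus", "Fagus sp."),
    ("tree", "Ulmaceae", "Ulmus", "Ulmus sp."),
    ("tree", "Betulaceae", "Betula", "Betula sp."),
)


@dataclass
class ClassProfile:
    """Idealized Raman signature of one pollen taxon.

    ``peaks`` is a list of ``(center cm^-1, amplitude a.u., width cm^-1)``
    Gaussian bands; ``baseline_coeffs`` are polynomial coefficients (constant
    first) evaluated on the axis rescaled to [-1, 1], modelling endogenous
    fluorescence; ``water_weight`` scales a broad water background.
    """

    name: str
    growth_habit: str
    family: str = ""
    genus: str = ""
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    baseline_coeffs: tuple[float, ...] = (0.0,)
    water_weight: float = 0.0

    def validate(self, axis_min: float, axis_max: float) -> None:
        if self.growth_habit not in GROWTH_HABITS:
            raise InvalidProfileError(
                f"unknown growth habit {self.growth_habit!r} for {self.name!r}"
            )
        if self.water_weight < 0:
            raise InvalidProfileError(f"negative water weight for {self.name!r}")
        for center, amp, width in self.peaks:
            if not axis_min <= center <= axis_max:
                raise InvalidProfileError(
                    f"peak at {center} cm^-1 of {self.name!r} lies outside the "
                    f"axis range [{axis_min}, {axis_max}]"
                )
            if width <= 0:
                raise InvalidProfileError(f"nonpositive peak width for {self.name!r}")
            if amp < 0:
                raise InvalidProfileError(f"negative peak amplitude for {self.name!r}")

    def clean_signal(self, axis: np.ndarray) -> np.ndarray:
        """Sum of the profile's Gaussian bands on ``axis`` (no baseline)."""
        axis = np.asarray(axis, dtype=float)
        signal = np.zeros_like(axis)
        for center, amp, width in self.peaks:
            signal += amp * np.exp(-0.5 * ((axis - center) / width) ** 2)
        return signal

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        """Fluorescence baseline evaluated on the rescaled axis."""
        nu = scaled_axis(axis)
        return np.polynomial.polynomial.polyval(nu, np.asarray(self.baseline_coeffs, float))


def scaled_axis(axis: np.ndarray) -> np.ndarray:
    """Axis linearly rescaled to [-1, 1]; used for all polynomial baselines."""
    axis = np.asarray(axis, dtype=float)
    lo, hi = axis[0], axis[-1]
    if hi == lo:
        return np.zeros_like(axis)
    return 2.0 * (axis - lo) / (hi - lo) - 1.0


def water_reference(axis: np.ndarray) -> np.ndarray:
    """Broad-band water background on ``axis``.

    Modelled as the OH bending band near 1640 cm^-1 plus the low-wavenumber
    tail of the OH stretch centred near 3250 cm^-1, on a small flat offset.
    Deterministic in the axis, so every module shares one curve.
    """
    axis = np.asarray(axis, dtype=float)
    bend = 0.6 * np.exp(-0.5 * ((axis - 1640.0) / 100.0) ** 2)
    stretch = 1.0 * np.exp(-0.5 * ((axis - 3250.0) / 230.0) ** 2)
    return bend + stretch + 0.05


def _class_rng(name: str, seed: int = 0) -> np.random.Generator:
    # crc32 keeps the per-class stream stable across sessions (unlike hash()).
    return np.random.default_rng((zlib.crc32(name.encode()) + seed) % 2**31)


def build_taxonomy_profiles(
    base_amplitude: float = 1.0,
    amplitude_spread: float = 0.5,
    water_weight: float = 0.5,
    seed: int = 0,
) -> list[ClassProfile]:
    """Profiles for the default 37-taxon screening panel.

    Every taxon carries the full band pool; class identity lives in a
    per-class multiplicative pattern over band amplitudes, drawn once from a
    stable per-class stream, plus a habit-level bias so that taxa sharing a
    growth habit are spectrally closer to each other than to other habits
    (the structure hierarchical clustering is expected to find).
    """
    habit_rngs = {h: _class_rng("habit:" + h, seed) for h in GROWTH_HABITS}
    habit_patterns = {
        h: 1.0 + 0.8 * r.uniform(-1.0, 1.0, size=len(RAMAN_BAND_POOL))
        for h, r in habit_rngs.items()
    }
    profiles = []
    for habit, family, genus, species in TAXONOMY_TABLE:
        rng = _class_rng(species, seed)
        pattern = 1.0 + amplitude_spread * rng.uniform(-1.0, 1.0, size=len(RAMAN_BAND_POOL))
        amps = base_amplitude * habit_patterns[habit] * pattern
        peaks = [
            (center, float(max(a, 0.02)), width)
            for (center, width), a in zip(RAMAN_BAND_POOL, amps)
        ]
        baseline = (
            float(2.0 + 0.5 * rng.uniform(-1, 1)),
            float(-0.6 + 0.2 * rng.uniform(-1, 1)),
            float(-0.3 + 0.2 * rng.uniform(-1, 1)),
        )
        profiles.append(
            ClassProfile(
                name=species,
                growth_habit=habit,
                family=family,
                genus=genus,
                peaks=peaks,
                baseline_coeffs=baseline,
                water_weight=float(water_weight * (1.0 + 0.2 * rng.uniform(-1, 1))),
            )
        )
    return profiles


def separable_profiles(
    n_classes: int = 4,
    habit: str = "herb",
    amplitude_delta: float = 0.5,
    base_amplitude: float = 1.0,
    water_weight: float = 0.5,
) -> list[ClassProfile]:
    """Classes sharing a spectral backbone, distinguished by controlled
    amplitude offsets.

    Each class raises a distinct subset of bands by ``amplitude_delta`` above
    the common backbone, so the between-class spectral contrast is set
    directly by one number.  Used for parameter-recovery studies where the
    contrast-to-noise ratio is swept.
    """
    if n_classes < 2 or n_classes > len(RAMAN_BAND_POOL):
        raise InvalidProfileError("n_classes must be between 2 and the band-pool size")
    profiles = []
    for k in range(n_classes):
        amps = np.full(len(RAMAN_BAND_POOL), base_amplitude)
        # rotate a two-band signature through the pool per class
        amps[k % len(RAMAN_BAND_POOL)] += amplitude_delta
        amps[(k + n_classes) % len(RAMAN_BAND_POOL)] += amplitude_delta
        peaks = [
            (center, float(a), width)
            for (center, width), a in zip(RAMAN_BAND_POOL, amps)
        ]
        profiles.append(
            ClassProfile(
                name=f"SynthClass{k:02d}",
                growth_habit=habit,
                family=f"SynthFamily{k:02d}",
                genus=f"SynthGenus{k:02d}",
                peaks=peaks,
                baseline_coeffs=(2.0, -0.5, -0.3),
                water_weight=water_weight,
            )
        )
    return profiles
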