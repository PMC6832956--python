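"""Core in-memory containers for Raman spectra.

A :class:`Spectrum` is a single particle's measurement: a strictly
increasing wavenumber axis (cm^-1), an intensity vector (a.u.) and free-form
metadata (labels, acquisition settings).  A :class:`SpectralDataset` bundles
many spectra sharing one axis together with a labels manifest, which is the
shape every downstream stage (preprocessing, clustering, classification)
operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Default acquisition metadata: 785 nm excitation at 140 mW, 0.5 s
#: integration per particle.
DEFAULT_ACQUISITION = {"excitation_nm": 785.0, "power_mW": 140.0, "integration_s": 0.5}

MANIFEST_COLUMNS = ("id", "species", "genus", "family", "growth_habit")


@dataclass
class Spectrum:
    """One Raman spectrum on a wavenumber axis.

    Parameters
    ----------
    axis : array of float
        Wavenumbers in cm^-1, strictly increasing.
    intensities : array of float
        Measured intensities, same length as ``axis``.
    meta : dict
        Identifier, taxonomy labels and acquisition fields.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.shape != self.intensities.shape or self.axis.ndim != 1:
            raise ValueError("axis and intensities must be 1-D and equal length")
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities: np.ndarray, **meta_updates: Any) -> "Spectrum":
        """Return a copy with new intensities (same axis) and updated meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.axis.copy(), np.asarray(intensities, dtype=float), meta)


@dataclass
class SpectralDataset:
    """Spectra sharing one axis, with a labels manifest.

    ``intensities`` is an (n_spectra, n_channels) matrix; ``manifest`` has one
    row per spectrum with at least the columns ``id``, ``species``, ``genus``,
    ``family`` and ``growth_habit``.
    """

    axis: np.ndarray
    intensities: np.ndarray
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.axis.size and self.intensities.size > 0:
            raise ValueError("intensity matrix width must match axis length")
        if len(self.manifest) != self.intensities.shape[0] and self.intensities.size > 0:
            raise ValueError("manifest length must match number of spectra")

    def __len__(self) -> int:
        return int(self.intensities.shape[0]) if self.intensities.size else 0

    def require_columns(self, *columns: str) -> None:
        missing = [c for c in columns if c not in self.manifest.columns]
        if missing:
            raise SchemaError(f"manifest is missing required column(s): {', '.join(missing)}")

    def spectrum(self, i: int) -> Spectrum:
        """Materialize row ``i`` as a :class:`Spectrum`."""
        meta = self.manifest.iloc[i].to_dict()
        return Spectrum(self.axis, self.intensities[i], meta)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return SpectralDataset(
            self.axis,
            self.intensities[mask],
            self.manifest.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask].reset_index(drop=True),
        )

    def class_means(self, by: str = "species") -> tuple[list[str], np.ndarray]:
        """Per-class mean spectra, classes in sorted label order."""
        self.require_columns(by)
        labels = sorted(self.manifest[by].unique())
        means = np.vstack(
            [self.intensities[(self.manifest[by] == lab).to_numpy()].mean(axis=0) for lab in labels]
        )
        return labels, means
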