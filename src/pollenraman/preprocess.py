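"""Raman spectral preprocessing chain.

The chain, in order: wavenumber calibration against a Raman-shift standard,
intensity calibration against a certified white lamp, cosmic spike removal,
extended multiplicative signal correction (EMSC) against a reference pollen
spectrum with a water interferent and a quadratic baseline, and area
normalization.  Each stage is available standalone; ``preprocess_pipeline``
composes them with per-spectrum provenance logging and drop isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal as scipy_signal

from .errors import (
    CalibrationError,
    DegenerateFitError,
    NormalizationError,
    RegionError,
)
from .spectrum import Spectrum, SpectralDataset

#: Raman shifts (cm^-1) of 4-acetaminophenol (paracetamol), the solid
#: wavenumber-shift standard of ASTM E1840.
ACETAMINOPHENOL_PEAKS_CM1 = (
    329.2, 390.9, 465.1, 504.0, 651.6, 710.8, 797.2, 834.5, 857.9, 968.7,
    1105.5, 1168.5, 1236.8, 1278.5, 1323.9, 1371.5, 1561.5, 1648.4,
    2931.1, 3064.6, 3102.4,
)


@dataclass
class RegionConfig:
    """Spectral windows used for clustering and classification."""

    fingerprint: tuple[float, float] = (758.0, 1800.0)
    high_wavenumber: tuple[float, float] = (2800.0, 3045.0)

    def __post_init__(self) -> None:
        for low, high in (self.fingerprint, self.high_wavenumber):
            if low >= high:
                raise ValueError("region bounds must satisfy low < high")


# ---------------------------------------------------------------------------
# wavenumber calibration


@dataclass
class WavenumberCalibration:
    """Polynomial pixel-index -> cm^-1 mapping fitted to standard bands."""

    coefficients: np.ndarray  # constant first
    degree: int
    residual_rms: float
    matched_pixels: np.ndarray
    matched_wavenumbers: np.ndarray

    def wavenumbers(self, pixel_axis: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(pixel_axis, float), self.coefficients)


def _refine_peak_subpixel(y: np.ndarray, idx: int) -> float:
    """Quadratic interpolation of a local maximum through three samples."""
    if idx <= 0 or idx >= y.size - 1:
        return float(idx)
    a, b, c = y[idx - 1], y[idx], y[idx + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(idx)
    return float(idx + 0.5 * (a - c) / denom)


def calibrate_wavenumber(
    standard_intensities: np.ndarray,
    peak_table: Sequence[float],
    degree: int = 3,
    prominence_frac: float = 0.05,
    match_tolerance: float = 25.0,
) -> WavenumberCalibration:
    """Fit the pixel -> wavenumber polynomial from a standard's spectrum.

    Local maxima are detected, refined to sub-pixel position by quadratic
    interpolation, paired with the literature peak table (order-based first,
    then nearest-within-tolerance after an initial fit), and least-squares
    fitted.  The fitted mapping must be strictly increasing over the pixel
    range.
    """
    y = np.asarray(standard_intensities, dtype=float)
    table = np.sort(np.asarray(peak_table, dtype=float))
    peaks, props = scipy_signal.find_peaks(y, prominence=prominence_frac * max(y.max(), 1e-30))
    if peaks.size > table.size:
        # keep the most prominent, restore pixel order
        order = np.argsort(props["prominences"])[::-1][: table.size]
        peaks = np.sort(peaks[order])
    if peaks.size < degree + 1:
        raise CalibrationError(
            f"matched only {peaks.size} peaks; need at least degree+1 = {degree + 1}"
        )
    if peaks.size < table.size:
        raise CalibrationError(
            f"detected {peaks.size} peaks but the table lists {table.size}; "
            "cannot establish an unambiguous match"
        )
    pixel_pos = np.array([_refine_peak_subpixel(y, int(p)) for p in peaks])

    # initial order-based pairing, then a nearest-within-tolerance pass
    coeffs = np.polynomial.polynomial.polyfit(pixel_pos, table, degree)
    predicted = np.polynomial.polynomial.polyval(pixel_pos, coeffs)
    keep_px, keep_wn = [], []
    for px, pred in zip(pixel_pos, predicted):
        j = int(np.argmin(np.abs(table - pred)))
        if abs(table[j] - pred) <= match_tolerance:
            keep_px.append(px)
            keep_wn.append(table[j])
    if len(keep_px) < degree + 1:
        raise CalibrationError(
            f"matched only {len(keep_px)} peaks within {match_tolerance} cm^-1; "
            f"need at least degree+1 = {degree + 1}"
        )
    px = np.asarray(keep_px)
    wn = np.asarray(keep_wn)
    coeffs = np.polynomial.polynomial.polyfit(px, wn, degree)

    full_pixels = np.arange(y.size, dtype=float)
    mapped = np.polynomial.polynomial.polyval(full_pixels, coeffs)
    if not np.all(np.diff(mapped) > 0):
        raise CalibrationError("fitted pixel-to-wavenumber mapping is not strictly increasing")
    resid = wn - np.polynomial.polynomial.polyval(px, coeffs)
    return WavenumberCalibration(
        coefficients=coeffs,
        degree=degree,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        matched_pixels=px,
        matched_wavenumbers=wn,
    )


# ---------------------------------------------------------------------------
# intensity calibration


@dataclass
class IntensityResponse:
    """Per-channel correction factors (certified / measured)."""

    factors: np.ndarray
    valid: np.ndarray  # boolean mask where the factors are trustworthy


def calibrate_intensity(
    measured_lamp: np.ndarray,
    certified_lamp: np.ndarray,
    smooth_window: int = 0,
) -> IntensityResponse:
    """Derive the system response correction from a white-lamp pair.

    Factors are certified/measured per channel; channels with nonpositive
    measured intensity are masked (factor 1).  More than 20% nonpositive
    channels voids the calibration.
    """
    measured = np.asarray(measured_lamp, dtype=float)
    certified = np.asarray(certified_lamp, dtype=float)
    if measured.shape != certified.shape:
        raise CalibrationError("lamp spectra must share one axis")
    valid = measured > 0
    if np.mean(~valid) > 0.20:
        raise CalibrationError(
            f"{np.mean(~valid):.0%} of measured lamp channels are nonpositive"
        )
    factors = np.ones_like(measured)
    factors[valid] = certified[valid] / measured[valid]
    if smooth_window and smooth_window > 1:
        factors = ndimage.uniform_filter1d(factors, size=int(smooth_window), mode="nearest")
    return IntensityResponse(factors=factors, valid=valid)


def apply_response(spectrum: Spectrum, response: IntensityResponse) -> Spectrum:
    """Multiply a spectrum by the response correction factors."""
    if spectrum.intensities.size != response.factors.size:
        raise CalibrationError("response factors do not match the spectrum axis")
    return spectrum.with_intensities(spectrum.intensities * response.factors)


# ---------------------------------------------------------------------------
# cosmic spike removal


def remove_cosmic_spikes(
    spectrum: Spectrum,
    width_threshold: int = 3,
    deviation_threshold: float = 8.0,
    baseline_window: int | None = None,
) -> tuple[Spectrum, np.ndarray]:
    """Remove narrow positive outliers (cosmic ray hits) from one spectrum.

    A channel is a spike candidate when its residual from a running-median
    baseline exceeds ``deviation_threshold`` robust scale units (1.4826 x
    MAD, floored at 0.1% of the intensity range so that noise-free spectra
    are not over-flagged).  The candidate's feature width is the contiguous
    support where the residual stays above half the trigger level: a cosmic
    hit drops back to baseline within a channel or two, while a genuine
    Raman band — even one whose tip barely crosses the trigger — stays
    elevated over many channels.  Only features narrower than
    ``width_threshold`` are replaced (by linear interpolation of their
    unflagged neighbors); unflagged channels are bit-identical to the input.
    """
    if width_threshold < 1:
        raise ValueError("width_threshold must be >= 1")
    y = spectrum.intensities
    # the median window must be wide relative to genuine bands so that a
    # band shows up as a *wide* residual feature while a cosmic hit stays
    # narrow; 21 channels covers typical band FWHMs on our default grid
    window = baseline_window or max(21, 4 * width_threshold + 3)
    baseline = ndimage.median_filter(y, size=window, mode="nearest")
    resid = y - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    ptp = float(np.ptp(y))
    scale = max(1.4826 * mad, 1e-3 * ptp if ptp > 0 else 1e-12, 1e-12)
    trigger = deviation_threshold * scale
    candidate = resid > trigger
    support = resid > 0.5 * trigger

    spike_channels: list[int] = []
    if candidate.any():
        # segment the half-trigger support into consecutive runs; a run is a
        # spike if it contains a triggered channel and is narrow
        idx = np.flatnonzero(support)
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        for run in runs:
            if run.size < width_threshold and candidate[run].any():
                spike_channels.extend(int(c) for c in run)
    spikes = np.asarray(sorted(spike_channels), dtype=int)
    if spikes.size == 0:
        return spectrum.with_intensities(y.copy()), spikes
    good = np.ones(y.size, dtype=bool)
    good[spikes] = False
    cleaned = y.copy()
    cleaned[spikes] = np.interp(spikes.astype(float), np.flatnonzero(good).astype(float), y[good])
    return spectrum.with_intensities(cleaned), spikes


# ---------------------------------------------------------------------------
# EMSC


def _scaled_axis(axis: np.ndarray) -> np.ndarray:
    lo, hi = axis[0], axis[-1]
    if hi == lo:
        return np.zeros_like(axis)
    return 2.0 * (axis - lo) / (hi - lo) - 1.0


@dataclass
class EMSCModel:
    """Basis of the EMSC decomposition on a fixed axis.

    Columns of the design matrix: reference spectrum r, water interferent w,
    and a quadratic polynomial in the axis rescaled to [-1, 1] for
    conditioning.
    """

    reference: np.ndarray
    water: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.water = np.asarray(self.water, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if not (self.reference.size == self.water.size == self.axis.size):
            raise ValueError("reference, water and axis must share one length")

    def design_matrix(self) -> np.ndarray:
        nu = _scaled_axis(self.axis)
        return np.column_stack(
            [self.reference, self.water, np.ones_like(nu), nu, nu**2]
        )


@dataclass
class EMSCCoefficients:
    """Fitted EMSC coefficients for one spectrum."""

    b: float        # multiplicative coefficient on the reference
    c_w: float      # water coefficient
    p0: float
    p1: float
    p2: float
    residual_norm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c_w, self.p0, self.p1, self.p2])


def emsc_fit(spectrum: Spectrum, model: EMSCModel) -> EMSCCoefficients:
    """Ordinary least-squares EMSC decomposition of one spectrum."""
    if spectrum.intensities.size != model.axis.size:
        raise DegenerateFitError("spectrum is not on the EMSC model axis")
    design = model.design_matrix()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateFitError("EMSC design matrix is rank deficient")
    coeffs, residual, *_ = np.linalg.lstsq(design, spectrum.intensities, rcond=None)
    resid_norm = float(np.linalg.norm(spectrum.intensities - design @ coeffs))
    return EMSCCoefficients(*(float(c) for c in coeffs), residual_norm=resid_norm)


def emsc_correct(
    spectrum: Spectrum,
    model: EMSCModel,
    coefficients: EMSCCoefficients | None = None,
    b_floor: float = 1e-6,
) -> Spectrum:
    """Invert the EMSC decomposition back to the reference scale.

    corrected = (y - c_w*w - p0 - p1*nu - p2*nu^2) / b.  A multiplicative
    coefficient with |b| below ``b_floor`` makes the division meaningless
    and raises ``DegenerateFitError``.
    """
    c = coefficients if coefficients is not None else emsc_fit(spectrum, model)
    if abs(c.b) < b_floor:
        raise DegenerateFitError(
            f"EMSC multiplicative coefficient |b| = {abs(c.b):.3g} below floor {b_floor:g}"
        )
    nu = _scaled_axis(model.axis)
    background = c.c_w * model.water + c.p0 + c.p1 * nu + c.p2 * nu**2
    return spectrum.with_intensities((spectrum.intensities - background) / c.b)


def build_reference(intensities: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Default EMSC reference: the dataset median spectrum, roughly
    detrended by removing its own least-squares quadratic baseline."""
    median = np.median(np.atleast_2d(intensities), axis=0)
    nu = _scaled_axis(np.asarray(axis, dtype=float))
    trend_coeffs = np.polynomial.polynomial.polyfit(nu, median, 2)
    detrended = median - np.polynomial.polynomial.polyval(nu, trend_coeffs)
    # shift onto a zero floor: the least-squares detrend leaves zero net
    # area, which would make downstream area normalization degenerate
    return detrended - detrended.min()


# ---------------------------------------------------------------------------
# normalization and cropping


def area_normalize(spectrum: Spectrum, region: tuple[float, float] | None = None) -> Spectrum:
    """Divide by the summed intensity over ``region`` (full axis default).

    After normalization the region's intensities sum to exactly 1.
    """
    if region is None:
        mask = np.ones(spectrum.axis.size, dtype=bool)
    else:
        mask = (spectrum.axis >= region[0]) & (spectrum.axis <= region[1])
        if not mask.any():
            raise RegionError(f"normalization region {region} does not overlap the axis")
    total = float(spectrum.intensities[mask].sum())
    if total <= 0:
        raise NormalizationError(f"nonpositive area {total:g} over the normalization region")
    return spectrum.with_intensities(spectrum.intensities / total)


def crop_region(spectrum: Spectrum, bounds: tuple[float, float]) -> Spectrum:
    """Keep channels with axis value in [low, high], order preserved."""
    low, high = bounds
    mask = (spectrum.axis >= low) & (spectrum.axis <= high)
    if not mask.any():
        raise RegionError(f"bounds {bounds} do not overlap the axis")
    return Spectrum(spectrum.axis[mask], spectrum.intensities[mask], dict(spectrum.meta))


def crop_matrix(axis: np.ndarray, matrix: np.ndarray, bounds: tuple[float, float]):
    """Vectorised :func:`crop_region` over a spectra matrix."""
    mask = (axis >= bounds[0]) & (axis <= bounds[1])
    if not mask.any():
        raise RegionError(f"bounds {bounds} do not overlap the axis")
    return axis[mask], matrix[:, mask]


# ---------------------------------------------------------------------------
# the composed pipeline


#: Canonical stage order of the preprocessing chain.
STAGE_ORDER = (
    "wavenumber_calibration",
    "intensity_calibration",
    "spike_removal",
    "emsc",
    "area_normalization",
)


@dataclass
class PipelineConfig:
    spike_width_threshold: int = 3
    spike_deviation_threshold: float = 8.0
    emsc_b_floor: float = 1e-6
    normalize_region: tuple[float, float] | None = None


@dataclass
class PipelineLog:
    """Provenance of one pipeline run: stage order, per-stage parameters,
    per-spectrum events (spike counts, drops with reasons)."""

    stages: list[str] = field(default_factory=list)
    stage_params: dict[str, dict] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0

    def record(self, stage: str, spectrum_id: str, **info) -> None:
        self.events.append({"stage": stage, "id": spectrum_id, **info})

    @property
    def dropped(self) -> list[dict]:
        return [e for e in self.events if e.get("dropped")]


def preprocess_pipeline(
    dataset: SpectralDataset,
    wavenumber_calibration: WavenumberCalibration | None = None,
    intensity_response: IntensityResponse | None = None,
    emsc_model: EMSCModel | None = None,
    config: PipelineConfig | None = None,
) -> tuple[SpectralDataset, PipelineLog]:
    """Run the full preprocessing chain over a dataset.

    Stages run in the canonical order (wavenumber calibration, intensity
    calibration, spike removal, EMSC, area normalization).  Calibration
    stages are skipped (and logged as skipped) when no calibration object is
    supplied, which is the synthetic-data case where spectra are already on
    a wavenumber axis.  A spectrum failing any stage is dropped with a
    logged reason; the rest proceed.
    """
    config = config or PipelineConfig()
    log = PipelineLog(n_in=len(dataset))
    if len(dataset) == 0:
        log.stages = list(STAGE_ORDER)
        return dataset, log

    axis = dataset.axis.copy()
    matrix = dataset.intensities.copy()
    ids = dataset.manifest["id"].tolist() if "id" in dataset.manifest.columns else [
        str(i) for i in range(len(dataset))
    ]

    # 1. wavenumber calibration: map a pixel axis to cm^-1, resample uniform
    log.stages.append("wavenumber_calibration")
    if wavenumber_calibration is not None:
        mapped = wavenumber_calibration.wavenumbers(np.arange(axis.size, dtype=float))
        uniform = np.linspace(mapped[0], mapped[-1], axis.size)
        matrix = np.vstack([np.interp(uniform, mapped, row) for row in matrix])
        axis = uniform
        log.stage_params["wavenumber_calibration"] = {
            "degree": wavenumber_calibration.degree,
            "residual_rms_cm1": wavenumber_calibration.residual_rms,
        }
    else:
        log.stage_params["wavenumber_calibration"] = {"skipped": True}

    # 2. intensity calibration
    log.stages.append("intensity_calibration")
    if intensity_response is not None:
        if intensity_response.factors.size != axis.size:
            raise CalibrationError("intensity response is not on the working axis")
        matrix = matrix * intensity_response.factors[None, :]
        log.stage_params["intensity_calibration"] = {
            "n_invalid_channels": int(np.sum(~intensity_response.valid))
        }
    else:
        log.stage_params["intensity_calibration"] = {"skipped": True}

    # 3. cosmic spike removal
    log.stages.append("spike_removal")
    log.stage_params["spike_removal"] = {
        "width_threshold": config.spike_width_threshold,
        "deviation_threshold": config.spike_deviation_threshold,
    }
    for i, sid in enumerate(ids):
        spec = Spectrum(axis, matrix[i])
        cleaned, spikes = remove_cosmic_spikes(
            spec, config.spike_width_threshold, config.spike_deviation_threshold
        )
        matrix[i] = cleaned.intensities
        log.record("spike_removal", sid, n_spikes=int(spikes.size))

    # 4. EMSC
    log.stages.append("emsc")
    if emsc_model is None:
        emsc_model = EMSCModel(
            reference=build_reference(matrix, axis),
            water=_default_water(axis),
            axis=axis,
        )
        log.stage_params["emsc"] = {"reference": "dataset-median (detrended)"}
    else:
        log.stage_params["emsc"] = {"reference": "user-supplied"}

    keep = np.ones(len(ids), dtype=bool)
    for i, sid in enumerate(ids):
        spec = Spectrum(axis, matrix[i])
        try:
            coeffs = emsc_fit(spec, emsc_model)
            corrected = emsc_correct(spec, emsc_model, coeffs, b_floor=config.emsc_b_floor)
        except DegenerateFitError as exc:
            keep[i] = False
            log.record("emsc", sid, dropped=True, reason=str(exc))
            continue
        matrix[i] = corrected.intensities
        log.record("emsc", sid, b=coeffs.b, residual_norm=coeffs.residual_norm)

    # 5. area normalization
    log.stages.append("area_normalization")
    log.stage_params["area_normalization"] = {"region": config.normalize_region}
    for i, sid in enumerate(ids):
        if not keep[i]:
            continue
        try:
            matrix[i] = area_normalize(
                Spectrum(axis, matrix[i]), config.normalize_region
            ).intensities
        except (NormalizationError, RegionError) as exc:
            keep[i] = False
            log.record("area_normalization", sid, dropped=True, reason=str(exc))

    out = SpectralDataset(axis, matrix[keep], dataset.manifest.iloc[keep].reset_index(drop=True))
    log.n_out = len(out)
    assert log.n_in == log.n_out + len(log.dropped), "pipeline lost spectra silently"
    return out, log


def _default_water(axis: np.ndarray) -> np.ndarray:
    # local import avoids a cycle with the simulation package
    from .simulate.profiles import water_reference

    return water_reference(axis)
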