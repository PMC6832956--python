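"""Bright-field pollen localization and stage geometry.

The detection chain converts a field of view to 8-bit grayscale, thresholds
its histogram (Otsu's between-class-variance criterion, particles on the
dark side), removes connected components outside the plausible pollen size
range, closes interior voids and dilates to stabilise blob shape, and
finally extracts per-blob statistics.  Companion routines convert pixel
coordinates to motorized-stage coordinates, fit the autofocus metric with a
Gaussian, and fit the slide tilt plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage import measure

from .errors import (
    DegenerateGeometryError,
    FocusFailureError,
    SingularTransformError,
)

# ITU-R 601 luminance weights, as used by standard grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class FoVImage:
    """One bright-field frame within the scan grid."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_index: tuple[int, int] = (0, 0)  # (row, col) in the raster

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.data.ndim not in (2, 3):
            raise ValueError("image must be 2-D grayscale or 3-D RGB")


@dataclass
class Blob:
    """A detected particle in pixel coordinates (x = column, y = row)."""

    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), exclusive upper bounds


@dataclass
class StageTransform:
    """Affine pixel -> stage map: stage = A @ (x, y) + offset (um)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise SingularTransformError("stage transform linear part is singular")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return (self.matrix @ np.atleast_2d(xy).T).T + self.offset

    def invert(self, stage_xy: np.ndarray) -> np.ndarray:
        return (np.linalg.inv(self.matrix) @ (np.atleast_2d(stage_xy) - self.offset).T).T


@dataclass
class FocusFit:
    """Gaussian + offset model of the autofocus metric along z."""

    amplitude: float
    center_um: float
    width_um: float
    offset: float


@dataclass
class TiltPlane:
    """Least-squares slide tilt: z = a*x + b*y + c (um)."""

    a: float
    b: float
    c: float
    residual_rms: float = 0.0

    def predict(self, x, y):
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c


@dataclass
class LocalizeConfig:
    """Parameters of the detection chain.

    Size bounds default to the pixel areas of 10-100 um diameter disks at
    the configured pixel size — the plausible pollen-grain range.
    """

    pixel_size_um: float = 1.0
    min_diameter_um: float = 10.0
    max_diameter_um: float = 100.0
    fill_iterations: int = 3
    dilate_iterations: int = 1

    def area_bounds_px(self) -> tuple[float, float]:
        to_px = 1.0 / self.pixel_size_um
        rmin = 0.5 * self.min_diameter_um * to_px
        rmax = 0.5 * self.max_diameter_um * to_px
        return float(np.pi * rmin**2), float(np.pi * rmax**2)


def to_grayscale8(image: np.ndarray) -> np.ndarray:
    """Convert any-bit-depth grayscale or RGB to full-range 8-bit.

    RGB is reduced by luminance weighting first; the result is min-max
    rescaled to [0, 255].  A constant image maps to all zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def histogram_threshold(gray8: np.ndarray) -> tuple[int | None, bool]:
    """Otsu threshold of an 8-bit image's 256-bin histogram.

    Returns ``(threshold, degenerate)``.  The threshold t maximizes the
    between-class variance of the split {0..t} vs {t+1..255}; ties resolve
    to the lowest t.  A single-valued histogram is flagged degenerate
    (threshold None) and yields an empty foreground downstream.
    """
    gray8 = np.asarray(gray8)
    if gray8.dtype != np.uint8:
        raise ValueError("histogram_threshold expects an 8-bit image")
    hist = np.bincount(gray8.ravel(), minlength=256).astype(float)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        return None, True
    p = hist / total
    omega = np.cumsum(p)                     # class-0 mass for t = 0..255
    mu = np.cumsum(p * np.arange(256))       # class-0 first moment
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b)), False


def segment_dark(gray8: np.ndarray) -> np.ndarray:
    """Binary foreground: pixels at or below the Otsu threshold (particles
    are the darker class under transmitted light)."""
    t, degenerate = histogram_threshold(gray8)
    if degenerate:
        return np.zeros(gray8.shape, dtype=bool)
    return gray8 <= t


def remove_particles_by_size(binary: np.ndarray, min_area: float, max_area: float) -> np.ndarray:
    """Drop 8-connected components with area outside [min_area, max_area]."""
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return binary.astype(bool).copy()
    areas = np.bincount(labels.ravel())
    keep = (areas >= min_area) & (areas <= max_area)
    keep[0] = False
    return keep[labels]


def fill_holes_and_dilate(
    binary: np.ndarray, fill_iterations: int = 3, dilate_iterations: int = 1
) -> np.ndarray:
    """Close interior voids, then dilate, both with a 3x3 window.

    The fill stage is an iterated morphological closing (k dilations then k
    erosions, outside-of-image treated as foreground for the erosion), which
    removes voids up to ~``fill_iterations`` px in radius while never
    shrinking the input.  The dilation stage is a plain iterated 3x3
    dilation.  Zero iterations of either stage is the identity.
    """
    if fill_iterations < 0 or dilate_iterations < 0:
        raise ValueError("iteration counts must be >= 0")
    out = np.asarray(binary, dtype=bool)
    if fill_iterations > 0:
        grown = ndimage.binary_dilation(out, SQUARE3, iterations=fill_iterations)
        out = ndimage.binary_erosion(grown, SQUARE3, iterations=fill_iterations, border_value=1)
        out |= np.asarray(binary, dtype=bool)  # guard monotonicity exactly
    if dilate_iterations > 0:
        out = ndimage.binary_dilation(out, SQUARE3, iterations=dilate_iterations)
    return out


def blob_analysis(binary: np.ndarray) -> list[Blob]:
    """Per-component statistics; 8-connectivity; sorted by centroid (y, x)."""
    labels = measure.label(np.asarray(binary, dtype=bool), connectivity=2)
    blobs = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        y0, x0, y1, x1 = region.bbox
        blobs.append(Blob(centroid=(float(cx), float(cy)), area=int(region.area), bbox=(x0, y0, x1, y1)))
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


def localize_pollen(fov: FoVImage, config: LocalizeConfig | None = None) -> list[Blob]:
    """Full detection chain on one field of view."""
    config = config or LocalizeConfig(pixel_size_um=fov.pixel_size_um)
    gray = to_grayscale8(fov.data)
    binary = segment_dark(gray)
    min_area, max_area = config.area_bounds_px()
    binary = remove_particles_by_size(binary, min_area, max_area)
    binary = fill_holes_and_dilate(binary, config.fill_iterations, config.dilate_iterations)
    return blob_analysis(binary)


def pixel_to_stage(
    blobs: Sequence[Blob],
    transform: StageTransform,
    frame_index: tuple[int, int] = (0, 0),
    frame_pitch_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Map blob centroids to stage coordinates (um).

    ``frame_index`` is (row, col) in the scan raster; the frame offset adds
    col * pitch_x to x and row * pitch_y to y.
    """
    if not blobs:
        return np.zeros((0, 2))
    pix = np.array([b.centroid for b in blobs], dtype=float)
    stage = transform.apply(pix)
    row, col = frame_index
    stage[:, 0] += col * frame_pitch_um[0]
    stage[:, 1] += row * frame_pitch_um[1]
    return stage


def variance_of_laplacian(image: np.ndarray) -> float:
    """Sharpness metric used as the autofocus objective in synthetic tests."""
    return float(np.var(ndimage.laplace(np.asarray(image, dtype=float))))


def _gaussian_offset(z, amplitude, center, width, offset):
    return offset + amplitude * np.exp(-0.5 * ((z - center) / width) ** 2)


def fit_focus_gaussian(z_positions: np.ndarray, focus_metric: np.ndarray) -> FocusFit:
    """Least-squares Gaussian + offset fit of the autofocus metric.

    The fitted center is the best-focus z.  Raises ``FocusFailureError`` if
    the optimiser fails or the center lands outside the sampled range.
    """
    z = np.asarray(z_positions, dtype=float)
    m = np.asarray(focus_metric, dtype=float)
    if z.size < 4:
        raise FocusFailureError("need at least 4 focus samples")
    if not np.all(np.diff(z) > 0):
        raise FocusFailureError("z positions must be strictly increasing")
    span = z[-1] - z[0]
    p0 = [m.max() - m.min(), z[np.argmax(m)], max(span / 6.0, 1e-6), m.min()]
    try:
        popt, _ = optimize.curve_fit(_gaussian_offset, z, m, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FocusFailureError(f"focus fit did not converge: {exc}") from exc
    amplitude, center, width, offset = popt
    width = abs(float(width))
    if not (z[0] <= center <= z[-1]) or amplitude <= 0:
        raise FocusFailureError(
            f"fitted focus center {center:.3f} um outside sampled range "
            f"[{z[0]:.3f}, {z[-1]:.3f}] or non-peaked metric"
        )
    return FocusFit(float(amplitude), float(center), width, float(offset))


def fit_tilt_plane(points: np.ndarray) -> TiltPlane:
    """Least-squares plane z = a*x + b*y + c through >= 3 stage points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateGeometryError("need at least 3 (x, y, z) points")
    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError("points are collinear; tilt plane undetermined")
    coeffs, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    residuals = pts[:, 2] - design @ coeffs
    return TiltPlane(
        float(coeffs[0]), float(coeffs[1]), float(coeffs[2]),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
    )
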