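"""Synthetic bright-field fields of view with ground-truth particle layout.

Transmitted-light contrast: the background sits near the top of the
intensity range and particles absorb, appearing as darker disks.  Some disks
carry a central bright void to exercise hole filling, and an optional linear
illumination gradient emulates imperfect Koehler alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import PlacementError


@dataclass
class FoVDesign:
    """Layout and noise settings for one synthetic field of view."""

    image_shape: tuple[int, int] = (480, 640)
    n_particles: int = 5
    radius_range: tuple[float, float] = (12.0, 25.0)
    min_separation: float = 80.0
    illumination_gradient: float = 0.0  # total relative intensity drop across columns
    noise_sd: float = 0.0               # in 8-bit intensity units
    hole_fraction: float = 0.3          # fraction of particles with a central void
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be positive and ordered")
        rmax = self.radius_range[1]
        if 2 * rmax >= min(self.image_shape):
            raise ValueError("particles must fit inside the image")


def _place_centers(design: FoVDesign, rng: np.random.Generator, max_tries: int = 2000):
    rows, cols = design.image_shape
    rmax = design.radius_range[1]
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < design.n_particles:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {design.n_particles} particles with "
                f"min_separation={design.min_separation} in {rows}x{cols} px"
            )
        tries += 1
        r = rng.uniform(*design.radius_range)
        cx = rng.uniform(rmax + 2, cols - rmax - 3)
        cy = rng.uniform(rmax + 2, rows - rmax - 3)
        if all((cx - x) ** 2 + (cy - y) ** 2 >= design.min_separation**2 for x, y in centers):
            centers.append((cx, cy))
            radii.append(r)
    return centers, radii


def generate_fov_image(design: FoVDesign) -> tuple[np.ndarray, list[dict]]:
    """Render one field of view.

    Returns the 8-bit image and a ground-truth list of dicts with keys
    ``cx``, ``cy`` (pixel centroid, x = column), ``radius`` and ``has_hole``.
    Deterministic per ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rows, cols = design.image_shape
    yy, xx = np.mgrid[0:rows, 0:cols]

    background = np.full((rows, cols), 230.0)
    if design.illumination_gradient:
        ramp = np.linspace(0.0, -design.illumination_gradient, cols)
        background = background * (1.0 + ramp)[None, :]

    image = background.copy()
    truth: list[dict] = []
    centers, radii = _place_centers(design, rng)
    for (cx, cy), radius in zip(centers, radii):
        dist2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disk = dist2 <= radius**2
        image[disk] = 60.0
        has_hole = bool(rng.random() < design.hole_fraction) and radius > 8
        if has_hole:
            hole = dist2 <= (radius * 0.25) ** 2
            image[hole] = 210.0
        truth.append({"cx": float(cx), "cy": float(cy), "radius": float(radius), "has_hole": has_hole})

    if design.noise_sd > 0:
        image = image + design.noise_sd * rng.standard_normal(image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8), truth
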