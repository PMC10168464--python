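"""Analytic test phantoms for 2D reconstruction experiments.

All phantoms are composed of ellipses (and axis-aligned rectangles for the
``blocks`` phantom) evaluated at pixel centers on the normalized square
[-1, 1] x [-1, 1]; intensities add, and every generated image lies in
[0, 1].

``shepp_logan`` uses the standard ten-ellipse head phantom with the
"modified" contrast values (skull 1.0, brain ~0.2, small inserts +0.1).
``forbild_like`` is a simplified head phantom in the FORBILD spirit — a
skull shell, brain, ventricle-like low-contrast ellipses and a small
high-contrast insert — documented by its table below; it is *not* the
licensed FORBILD parameter set.  ``thorax`` is a structured synthetic
chest-like phantom (body ellipse, two lungs, spine, vessels and small
nodules as fine structure) used where a real clinical slice would
otherwise be needed.  ``disk`` is a uniform disk, by default centered at
the grid rotation center so its sinogram is rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "phantom_value_at",
    "SHEPP_LOGAN_ELLIPSES",
    "FORBILD_LIKE_ELLIPSES",
    "PHANTOM_KINDS",
]

# Each row: (intensity, semi-axis a (x), semi-axis b (y), x0, y0, rotation deg).
# Standard ten-ellipse head phantom, modified contrast values.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.10, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.10, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)

# Simplified head phantom: skull shell, brain, two ventricle-like ellipses,
# low-contrast frontal disk, small high-contrast insert.
FORBILD_LIKE_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.72, 0.95, 0.0, 0.0, 0.0),
    (-0.55, 0.66, 0.88, 0.0, 0.0, 0.0),
    (-0.10, 0.12, 0.30, 0.25, -0.05, -15.0),
    (-0.10, 0.12, 0.30, -0.25, -0.05, 15.0),
    (0.05, 0.14, 0.14, 0.0, 0.45, 0.0),
    (0.30, 0.04, 0.04, 0.0, -0.45, 0.0),
    (0.10, 0.05, 0.10, 0.35, 0.40, 30.0),
)

PHANTOM_KINDS = ("shepp_logan", "forbild_like", "disk", "blocks")


@dataclass(frozen=True)
class PhantomSpec:
    """What to generate: phantom family, grid size and intensity range."""

    kind: str
    size: tuple[int, int]
    intensity_range: tuple[float, float] = (0.0, 1.0)
    disk_radius: float = 0.35  # normalized units, disk phantom only

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.size[0] < 2 or self.size[1] < 2:
            raise ValueError("phantom size must be at least 2x2")


def _normalized_coords(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (x right, y up) coordinates of pixel centers in [-1, 1]."""
    n_x, n_y = size
    half_r = (n_x - 1) / 2
    half_c = (n_y - 1) / 2
    i = np.arange(n_x)[:, None]
    j = np.arange(n_y)[None, :]
    x = (j - half_c) / half_c
    y = (half_r - i) / half_r
    return np.broadcast_to(x, size), np.broadcast_to(y, size)


def _inside_ellipse(x, y, a, b, x0, y0, phi_deg):
    phi = np.deg2rad(phi_deg)
    xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
    yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def phantom_value_at(table, x: float, y: float) -> float:
    """Sum of intensities of the table's ellipses containing point (x, y)."""
    total = 0.0
    for val, a, b, x0, y0, phi in table:
        if _inside_ellipse(np.asarray(x), np.asarray(y), a, b, x0, y0, phi):
            total += val
    return total


def _from_ellipses(size, table) -> np.ndarray:
    x, y = _normalized_coords(size)
    img = np.zeros(size)
    for val, a, b, x0, y0, phi in table:
        img[_inside_ellipse(x, y, a, b, x0, y0, phi)] += val
    # intensity sums like 1 - 0.8 - 0.2 land at +/- one ulp of 0
    return np.clip(img, 0.0, 1.0)


def _disk(size, radius, center=None) -> np.ndarray:
    """Uniform unit disk; ``center`` in pixel-index units, default n/2 (the
    default rotation center of :class:`~fladmm.geometry.ImageGrid`)."""
    n_x, n_y = size
    if center is None:
        center = (n_x / 2, n_y / 2)
    i = np.arange(n_x)[:, None]
    j = np.arange(n_y)[None, :]
    r_pix = radius * min(n_x, n_y) / 2
    return ((i - center[0]) ** 2 + (j - center[1]) ** 2 <= r_pix**2).astype(float)


def _blocks(size) -> np.ndarray:
    """Chest-like synthetic phantom: body, lungs, spine, vessels, nodules.

    Unlike the piecewise-constant head phantoms, this one carries smooth
    intensity modulations (soft-tissue gradient, lung-parenchyma bumps).
    Real CT slices are not piecewise constant, so a TV reconstruction from
    sparse views cannot recover them exactly; the smooth components give
    this phantom the same property, which is what makes it a meaningful
    stand-in in sparse-view solver comparisons.
    """
    x, y = _normalized_coords(size)
    img = np.zeros(size)
    body = _inside_ellipse(x, y, 0.90, 0.65, 0.0, 0.0, 0.0)
    img[body] += 0.50
    # smooth soft-tissue variation across the body
    img += body * 0.10 * np.exp(-((x - 0.1) ** 2 + (y + 0.1) ** 2) / 0.5)
    lungs = np.zeros(size, dtype=bool)
    for sx in (-1.0, 1.0):
        lungs |= _inside_ellipse(x, y, 0.32, 0.45, sx * 0.42, 0.05, sx * 8.0)
    img[lungs] -= 0.40
    # smooth parenchyma texture inside the lungs
    for sx, amp, w in ((-1.0, 0.12, 0.04), (1.0, 0.10, 0.06)):
        img += lungs * amp * np.exp(-((x - sx * 0.42) ** 2 + (y - 0.1) ** 2) / w)
    img[_inside_ellipse(x, y, 0.10, 0.12, 0.0, -0.45, 0.0)] += 0.45  # spine
    img[_inside_ellipse(x, y, 0.12, 0.16, 0.0, 0.05, 0.0)] += 0.25  # heart/mediastinum
    # fine structure: vessels (thin rectangles) and nodules inside the lungs
    for sx in (-1.0, 1.0):
        img[(np.abs(x - sx * 0.42) < 0.02) & (np.abs(y - 0.05) < 0.30)] += 0.20
        img[(np.abs(x - sx * 0.42) < 0.20) & (np.abs(y - 0.20) < 0.015)] += 0.15
        img[_inside_ellipse(x, y, 0.030, 0.030, sx * 0.55, -0.15, 0.0)] += 0.25
        img[_inside_ellipse(x, y, 0.018, 0.018, sx * 0.30, 0.30, 0.0)] += 0.25
    return np.clip(img, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate the deterministic phantom image described by ``spec``."""
    if spec.kind == "shepp_logan":
        img = _from_ellipses(spec.size, SHEPP_LOGAN_ELLIPSES)
    elif spec.kind == "forbild_like":
        img = _from_ellipses(spec.size, FORBILD_LIKE_ELLIPSES)
    elif spec.kind == "disk":
        img = _disk(spec.size, spec.disk_radius)
    else:
        img = _blocks(spec.size)
    lo, hi = spec.intensity_range
    if (lo, hi) != (0.0, 1.0):
        img = lo + (hi - lo) * img
    return img
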