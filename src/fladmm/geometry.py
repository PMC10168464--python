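"""Image-grid and parallel-beam scan-geometry descriptions.

Coordinate conventions
----------------------
Pixels are indexed 0-based as ``(i, j)`` = (row, column).  The world
coordinates of the center of pixel ``(i, j)`` are

    x = (j - center_col) * pixel_size
    y = (center_row - i) * pixel_size

so the rotation center (``center_row``, ``center_col``, in pixel-index
units) sits at the world origin and the y axis points up.  The default
rotation center is ``(n - 1) / 2 + 0.5 = n / 2``, which on a 256 grid puts
the origin at index 128 (the conventional "[128, 128]" of CT simulation
setups).

A parallel-beam view at angle ``theta`` measures line integrals along rays
perpendicular to the detector axis ``(cos theta, sin theta)``; a point
``(x, y)`` projects to detector coordinate ``t = x cos(theta) + y sin(theta)``.
Detector bin centers default to ``-(n_bins/2 - 1) ... n_bins/2`` times
``bin_length`` (the "[−127, 128]" layout for 256 bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "ScanGeometry", "uniform_angles"]


def uniform_angles(n_angles: int) -> np.ndarray:
    """View angles uniformly distributed on the half-open range [0, pi).

    The half-open convention avoids duplicating the 0 / pi view, which
    measure the same line integrals (up to detector reversal).
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    return np.arange(n_angles) * np.pi / n_angles


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel reconstruction grid of ``n_x`` rows by ``n_y`` columns."""

    n_x: int
    n_y: int
    pixel_size: float = 1.0
    center_row: float | None = None
    center_col: float | None = None

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid must be at least 2x2")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.center_row is None:
            object.__setattr__(self, "center_row", (self.n_x - 1) / 2 + 0.5)
        if self.center_col is None:
            object.__setattr__(self, "center_col", (self.n_y - 1) / 2 + 0.5)

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_y

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x, self.n_y)

    def pixel_world_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World ``(x, y)`` coordinates of every pixel center, each (n_x, n_y)."""
        i = np.arange(self.n_x)[:, None]
        j = np.arange(self.n_y)[None, :]
        x = (j - self.center_col) * self.pixel_size
        y = (self.center_row - i) * self.pixel_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y, self.shape).copy()


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam acquisition: ``n_bins`` detector bins by ``n_angles`` views."""

    n_bins: int
    n_angles: int
    angles: np.ndarray = None  # type: ignore[assignment]
    bin_length: float = 1.0
    detector_offsets: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if not self.bin_length > 0:
            raise ValueError("bin_length must be positive")
        angles = self.angles
        if angles is None:
            angles = uniform_angles(self.n_angles)
        angles = np.asarray(angles, dtype=float)
        if angles.shape != (self.n_angles,):
            raise ValueError("angles length must equal n_angles")
        if np.any(angles < 0) or np.any(angles >= np.pi):
            raise ValueError("angles must lie in [0, pi)")
        if self.n_angles > 1 and np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", angles)

        offs = self.detector_offsets
        if offs is None:
            offs = (np.arange(self.n_bins) - (self.n_bins / 2 - 1)) * self.bin_length
        offs = np.asarray(offs, dtype=float)
        if offs.shape != (self.n_bins,):
            raise ValueError("detector_offsets length must equal n_bins")
        if self.n_bins > 1 and not np.allclose(np.diff(offs), self.bin_length):
            raise ValueError("detector_offsets must be uniformly spaced by bin_length")
        object.__setattr__(self, "detector_offsets", offs)

    @property
    def n_meas(self) -> int:
        return self.n_bins * self.n_angles

    @property
    def shape(self) -> tuple[int, int]:
        """Sinogram shape: (detector bins, view angles)."""
        return (self.n_bins, self.n_angles)
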