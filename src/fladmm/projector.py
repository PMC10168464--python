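"""Pixel-driven 2D parallel-beam Radon transform and its exact adjoint.

The discrete imaging model is ``g = A u`` with ``u`` an (n_x, n_y)
attenuation map and ``g`` an (n_bins, n_angles) sinogram.  The projector is
pixel-driven: for each view, every pixel center is projected onto the
detector axis and its value is linearly interpolated into the two nearest
bins.  Interpolation weights are nonnegative and, for a pixel fully inside
the detector range, sum to ``pixel_size**2 / bin_length`` (exactly 1 in the
unit-spacing setups used throughout).  Backprojection reuses the identical
weights, so ``forward_project`` / ``back_project`` form an exactly matched
adjoint pair — a property the iterative solvers rely on.

Pixels whose projection falls outside the detector contribute nothing; an
unmatched ray-driven backprojector is deliberately not offered.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import ImageGrid, ScanGeometry

__all__ = [
    "LinearMap",
    "MatrixOperator",
    "RadonTransform",
    "forward_project",
    "back_project",
    "as_matrix",
    "spectral_norm_sq",
]


class LinearMap:
    """A linear operator with a matched adjoint.

    Subclasses implement :meth:`apply` and :meth:`apply_adjoint` and expose
    ``in_shape`` / ``out_shape``.  The adjoint contract
    ``<A x, y> == <x, A^T y>`` must hold to numerical round-off; the solvers
    and the power method assume it.
    """

    in_shape: tuple[int, ...]
    out_shape: tuple[int, ...]

    def apply(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def apply_adjoint(self, y: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class MatrixOperator(LinearMap):
    """Wrap an explicit (dense or sparse) matrix as a LinearMap.

    ``in_shape`` / ``out_shape`` default to flat vectors but may be set to
    any shapes with matching sizes, in which case inputs are raveled
    C-order and outputs reshaped.
    """

    def __init__(self, matrix, in_shape=None, out_shape=None):
        self.matrix = matrix
        m, n = matrix.shape
        self.in_shape = (n,) if in_shape is None else tuple(in_shape)
        self.out_shape = (m,) if out_shape is None else tuple(out_shape)
        if int(np.prod(self.in_shape)) != n or int(np.prod(self.out_shape)) != m:
            raise ValueError("shape metadata inconsistent with matrix")
        self._adj = matrix.T.tocsr() if sp.issparse(matrix) else matrix.T

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ np.asarray(x).ravel()).reshape(self.out_shape)

    def apply_adjoint(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self._adj @ np.asarray(y).ravel()).reshape(self.in_shape)


def _check_image(u: np.ndarray, grid: ImageGrid) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != grid.shape:
        raise ValueError(f"image shape {u.shape} does not match grid {grid.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("image contains non-finite values")
    return u


def _check_sino(s: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != geom.shape:
        raise ValueError(f"sinogram shape {s.shape} does not match geometry {geom.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("sinogram contains non-finite values")
    return s


def _bin_weights(grid: ImageGrid, geom: ScanGeometry, angle_index: int):
    """Interpolation footprint of every pixel for one view.

    Returns ``(i0, w0, w1, inside0, inside1)`` where ``i0`` is the left bin
    index of each pixel (shape (n_x, n_y)), ``w0``/``w1`` the weights into
    bins ``i0``/``i0+1`` and the masks flag footprints that land on the
    detector.
    """
    theta = geom.angles[angle_index]
    x, y = grid.pixel_world_coords()
    t = x * np.cos(theta) + y * np.sin(theta)
    f = (t - geom.detector_offsets[0]) / geom.bin_length
    i0 = np.floor(f).astype(np.int64)
    frac = f - i0
    scale = grid.pixel_size**2 / geom.bin_length
    w0 = (1.0 - frac) * scale
    w1 = frac * scale
    inside0 = (i0 >= 0) & (i0 <= geom.n_bins - 1)
    inside1 = (i0 + 1 >= 0) & (i0 + 1 <= geom.n_bins - 1)
    return i0, w0, w1, inside0, inside1


def forward_project(u: np.ndarray, grid: ImageGrid, geom: ScanGeometry) -> np.ndarray:
    """Pixel-driven Radon transform ``A u`` -> sinogram of shape (n_bins, n_angles)."""
    u = _check_image(u, grid)
    sino = np.zeros(geom.shape)
    for a in range(geom.n_angles):
        i0, w0, w1, m0, m1 = _bin_weights(grid, geom, a)
        col = np.zeros(geom.n_bins)
        np.add.at(col, i0[m0], w0[m0] * u[m0])
        np.add.at(col, i0[m1] + 1, w1[m1] * u[m1])
        sino[:, a] = col
    return sino


def back_project(s: np.ndarray, grid: ImageGrid, geom: ScanGeometry) -> np.ndarray:
    """Exact adjoint ``A^T s`` of :func:`forward_project` (same weights)."""
    s = _check_sino(s, geom)
    img = np.zeros(grid.shape)
    for a in range(geom.n_angles):
        i0, w0, w1, m0, m1 = _bin_weights(grid, geom, a)
        img[m0] += w0[m0] * s[i0[m0], a]
        img[m1] += w1[m1] * s[i0[m1] + 1, a]
    return img


def _system_matrix(grid: ImageGrid, geom: ScanGeometry) -> sp.csr_matrix:
    """Assemble the sparse system matrix (rows = raveled sinogram entries)."""
    rows, cols, vals = [], [], []
    pix = np.arange(grid.n_pixels).reshape(grid.shape)
    for a in range(geom.n_angles):
        i0, w0, w1, m0, m1 = _bin_weights(grid, geom, a)
        rows.append(i0[m0] * geom.n_angles + a)
        cols.append(pix[m0])
        vals.append(w0[m0])
        rows.append((i0[m1] + 1) * geom.n_angles + a)
        cols.append(pix[m1])
        vals.append(w1[m1])
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_meas, grid.n_pixels),
    )
    return mat.tocsr()


def as_matrix(grid: ImageGrid, geom: ScanGeometry, max_entries: int = 10**6) -> sp.csr_matrix:
    """Explicit sparse system matrix for small problems (test oracle).

    Refuses when the dense-equivalent size ``N * M`` exceeds ``max_entries``;
    production solvers use :class:`RadonTransform`, which stores only the
    sparse nonzeros.
    """
    dense_equiv = grid.n_pixels * geom.n_meas
    if dense_equiv > max_entries:
        raise ValueError(
            f"explicit matrix would be {dense_equiv} dense-equivalent entries "
            f"(cap {max_entries}); use RadonTransform instead"
        )
    return _system_matrix(grid, geom)


class RadonTransform(LinearMap):
    """The system matrix ``A`` as a fast matrix-backed LinearMap.

    The sparse matrix is assembled once at construction from the same
    pixel-driven weights as :func:`forward_project`; applying it is a CSR
    mat-vec, which keeps the iterative solvers cheap.
    """

    def __init__(self, grid: ImageGrid, geom: ScanGeometry):
        self.grid = grid
        self.geom = geom
        self.in_shape = grid.shape
        self.out_shape = geom.shape
        self._mat = _system_matrix(grid, geom)
        self._adj = self._mat.T.tocsr()

    def apply(self, u: np.ndarray) -> np.ndarray:
        u = _check_image(u, self.grid)
        return (self._mat @ u.ravel()).reshape(self.out_shape)

    def apply_adjoint(self, s: np.ndarray) -> np.ndarray:
        s = _check_sino(s, self.geom)
        return (self._adj @ s.ravel()).reshape(self.in_shape)


def spectral_norm_sq(
    op: LinearMap,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[float, bool]:
    """Largest eigenvalue of ``op^T op`` by power iteration.

    Returns ``(lambda_max, converged)``.  Deterministic given ``seed`` (the
    start vector is drawn from a seeded uniform RNG).  A zero operator
    returns ``(0.0, True)``.  ``tol`` is the relative eigenvalue change
    between sweeps.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=op.in_shape)
    nx = np.linalg.norm(x)
    if nx == 0:  # pragma: no cover - measure-zero draw
        x = np.ones(op.in_shape)
        nx = np.linalg.norm(x)
    x = x / nx
    lam = 0.0
    for _ in range(max_iter):
        v = op.apply_adjoint(op.apply(x))
        nv = np.linalg.norm(v)
        if nv == 0:
            return 0.0, True
        lam_new = float(np.vdot(x, v).real)
        x = v / nv
        if lam > 0 and abs(lam_new - lam) <= tol * lam_new:
            return lam_new, True
        lam = lam_new
    return lam, False
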