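"""Landmark-initialized rigid alignment and B-spline deformable registration
with a mean-squared-error cost.

The deformable stage optimizes a cubic B-spline displacement field over a
coarse-to-fine image pyramid with L-BFGS and a bending-energy penalty on the
control grid.  Fields use pull-back semantics: ``output(x) = moving(x + d(x))``
with ``d`` in physical mm on the fixed grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import nibabel as nib
import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import minimize

from .image_core import GeometryError, Volume, modality_fill_value

__all__ = [
    "RigidTransform",
    "DeformationField",
    "RegistrationParams",
    "OptimizationError",
    "rigid_from_landmarks",
    "initial_alignment",
    "bspline_register",
    "apply_deformation",
    "write_field",
    "read_field",
]

log = logging.getLogger(__name__)


class OptimizationError(RuntimeError):
    """Non-finite cost encountered during optimization."""


@dataclass(frozen=True)
class RigidTransform:
    """Maps fixed-space physical points to moving-space: p' = R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        if rot.shape != (3, 3) or not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise GeometryError("rotation must be 3x3 orthonormal")
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise GeometryError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


@dataclass
class DeformationField:
    """Dense per-voxel displacements (mm) on the fixed grid, shape (*grid, 3)."""

    displacements: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = dc_field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[3] != 3:
            raise GeometryError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise GeometryError("displacement field contains non-finite values")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zero_like(cls, v: Volume) -> "DeformationField":
        return cls(np.zeros(v.shape + (3,)), v.spacing, v.origin, v.orientation)


@dataclass
class RegistrationParams:
    """B-spline registration settings.

    ``iterations_per_level`` may be an int (same budget at every level) or a
    sequence, coarsest level first.  ``subsample`` of (1, 1, 1) means the
    finest pyramid level runs at full resolution.
    """

    grid_spacing_mm: float = 40.0
    pyramid_levels: int = 3
    iterations_per_level: int | tuple[int, ...] = 100
    subsample: tuple[int, int, int] = (1, 1, 1)
    regularization_weight: float = 0.01
    metric: str = "mse"

    def __post_init__(self) -> None:
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be > 0")
        if any(s < 1 for s in self.subsample):
            raise ValueError("subsample factors must be >= 1")
        if self.metric != "mse":
            raise ValueError("only the mean-squared-error metric is supported")

    def level_iterations(self) -> list[int]:
        it = self.iterations_per_level
        if isinstance(it, int):
            return [it] * self.pyramid_levels
        it = list(it)
        if len(it) != self.pyramid_levels:
            raise ValueError("iterations_per_level length must match pyramid_levels")
        return it


# --------------------------------------------------------------------------
# Rigid alignment
# --------------------------------------------------------------------------

def rigid_from_landmarks(fixed_pts, moving_pts) -> RigidTransform:
    """Least-squares rigid transform (Procrustes) from >=3 matched points."""
    f = np.asarray(fixed_pts, dtype=float)
    m = np.asarray(moving_pts, dtype=float)
    if f.shape != m.shape or f.ndim != 2 or f.shape[1] != 3:
        raise GeometryError("point sets must be matched (n, 3) arrays")
    if f.shape[0] < 3:
        raise GeometryError("at least 3 matched landmarks are required")
    fc = f - f.mean(axis=0)
    if np.linalg.matrix_rank(fc, tol=1e-8) < 2:
        raise GeometryError("landmarks are collinear")
    mc = m - m.mean(axis=0)
    h = fc.T @ mc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = m.mean(axis=0) - rot @ f.mean(axis=0)
    return RigidTransform(rot, t)


def initial_alignment(fixed_pts, moving_pts) -> RigidTransform:
    """Rigid initialization tolerant of sparse landmark sets.

    With >=3 non-collinear points this is the full Procrustes solution; with
    1-2 points (e.g. the two greater trochanters) it degrades to the
    translation of the centroids.
    """
    f = np.asarray(fixed_pts, dtype=float).reshape(-1, 3)
    m = np.asarray(moving_pts, dtype=float).reshape(-1, 3)
    if f.shape != m.shape or f.shape[0] == 0:
        raise GeometryError("landmark sets must be matched and non-empty")
    if f.shape[0] >= 3 and np.linalg.matrix_rank(f - f.mean(axis=0), tol=1e-8) >= 2:
        return rigid_from_landmarks(f, m)
    return RigidTransform(np.eye(3), m.mean(axis=0) - f.mean(axis=0))


# --------------------------------------------------------------------------
# Cubic B-spline machinery (axis-aligned fixed grid)
# --------------------------------------------------------------------------

def _bspline_weights_1d(coords_mm: np.ndarray, h: float, n_ctrl: int) -> sparse.csr_matrix:
    """Sparse (n_pts, n_ctrl) matrix of cubic B-spline weights.

    Control point j sits at physical position (j - 1) * h, so the support of
    the spline covers the whole [0, L] domain with one marginal row of
    control points on each side.
    """
    u = coords_mm / h + 1.0
    i0 = np.floor(u).astype(int)
    t = u - i0
    t2, t3 = t * t, t * t * t
    w = np.empty((coords_mm.size, 4))
    w[:, 0] = (1 - 3 * t + 3 * t2 - t3) / 6.0
    w[:, 1] = (4 - 6 * t2 + 3 * t3) / 6.0
    w[:, 2] = (1 + 3 * t + 3 * t2 - 3 * t3) / 6.0
    w[:, 3] = t3 / 6.0
    cols = i0[:, None] + np.arange(-1, 3)[None, :]
    cols = np.clip(cols, 0, n_ctrl - 1)
    rows = np.repeat(np.arange(coords_mm.size), 4)
    return sparse.csr_matrix(
        (w.ravel(), (rows, cols.ravel())), shape=(coords_mm.size, n_ctrl)
    )


def _apply_along_axis(mat: sparse.spmatrix, arr: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(arr, axis, 0)
    lead = moved.shape[0]
    flat = moved.reshape(lead, -1)
    out = mat @ flat
    out = out.reshape((mat.shape[0],) + moved.shape[1:])
    return np.moveaxis(out, 0, axis)


class _BSplineModel:
    """Tensor-product cubic B-spline displacement on an axis-aligned grid."""

    def __init__(self, extent_mm: np.ndarray, grid_spacing_mm: float):
        self.h = float(grid_spacing_mm)
        self.n_ctrl = tuple(int(np.floor(e / self.h)) + 4 for e in extent_mm)

    def weights_for(self, coords_axes: list[np.ndarray]) -> list[sparse.csr_matrix]:
        return [
            _bspline_weights_1d(c, self.h, n)
            for c, n in zip(coords_axes, self.n_ctrl)
        ]

    def evaluate(self, weights, coeffs: np.ndarray) -> np.ndarray:
        out = coeffs
        for axis, w in enumerate(weights):
            out = _apply_along_axis(w, out, axis)
        return out

    def adjoint(self, weights, grad_dense: np.ndarray) -> np.ndarray:
        out = grad_dense
        for axis, w in enumerate(weights):
            out = _apply_along_axis(w.T.tocsr(), out, axis)
        return out

    def bending_energy(self, coeffs: np.ndarray):
        """Sum of squared second differences along each control axis."""
        energy = 0.0
        grad = np.zeros_like(coeffs)
        for axis in range(3):
            c = np.moveaxis(coeffs, axis, 0)
            d2 = c[2:] - 2 * c[1:-1] + c[:-2]
            energy += float(np.sum(d2 * d2))
            g = np.moveaxis(grad, axis, 0)
            g[2:] += 2 * d2
            g[1:-1] += -4 * d2
            g[:-2] += 2 * d2
        return energy, grad


def _level_sigma_vox(shape, factor: int) -> list[float]:
    return [factor / 2.0 if n > factor else 0.0 for n in shape]


def _downsample(data: np.ndarray, spacing: np.ndarray, factor: int):
    if factor == 1:
        return data.astype(np.float64), spacing.copy()
    sigma = _level_sigma_vox(data.shape, factor)
    sm = ndimage.gaussian_filter(data.astype(np.float64), sigma=sigma)
    return sm[::factor, ::factor, ::factor], spacing * factor


def _sample(data: np.ndarray, idx: np.ndarray, order: int, cval: float) -> np.ndarray:
    """map_coordinates with edge snapping.

    Coordinates a rounding error beyond the last voxel (e.g. from a
    numerically near-identity rigid transform) must sample the edge, not the
    constant fill.
    """
    idx = idx.copy()
    for a in range(3):
        n = float(data.shape[a] - 1)
        c = idx[..., a]
        np.copyto(c, 0.0, where=(c > -1e-9) & (c < 0.0))
        np.copyto(c, n, where=(c > n) & (c < n + 1e-9))
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    return ndimage.map_coordinates(
        data, coords, order=order, mode="constant", cval=cval, prefilter=False
    ).reshape(idx.shape[:-1])


def _require_axis_aligned(v: Volume, role: str) -> None:
    if not np.allclose(v.orientation, np.eye(3), atol=1e-6):
        raise GeometryError(
            f"{role} volume must be in canonical (identity) orientation for "
            "registration; reorient at load"
        )


def bspline_register(
    fixed: Volume,
    moving: Volume,
    init: RigidTransform | None = None,
    params: RegistrationParams | None = None,
) -> DeformationField:
    """Deformable registration of ``moving`` onto ``fixed``'s grid.

    Returns the composed rigid + B-spline displacement as one dense field;
    the final MSE never exceeds the rigid-only MSE (the spline component is
    dropped if optimization fails to improve it).
    """
    params = params or RegistrationParams()
    init = init or RigidTransform.identity()
    _require_axis_aligned(fixed, "fixed")

    extent = (np.array(fixed.shape) - 1) * fixed.spacing
    model = _BSplineModel(extent, params.grid_spacing_mm)
    coeffs = np.zeros(model.n_ctrl + (3,))

    fill = modality_fill_value(moving.modality_tag)
    mov64 = moving.data.astype(np.float64)

    factors = [2 ** (params.pyramid_levels - 1 - i)
               for i in range(params.pyramid_levels)]
    iters = params.level_iterations()
    lam = params.regularization_weight

    for level, (factor, maxiter) in enumerate(zip(factors, iters)):
        fdata, fspacing = _downsample(fixed.data, fixed.spacing, factor)
        # smooth the moving image to the same physical scale as this level
        if factor == 1:
            mov_level = mov64
        else:
            sigma_mm = np.array(_level_sigma_vox(fixed.shape, factor)) * fixed.spacing
            mov_level = ndimage.gaussian_filter(mov64,
                                                sigma=sigma_mm / moving.spacing)
        grad_axes = np.gradient(mov_level, *moving.spacing)  # d/dmm

        shape = fdata.shape
        axes_mm = [np.arange(n) * s for n, s in zip(shape, fspacing)]
        weights = model.weights_for(axes_mm)

        # world coordinates of the fixed grid after the rigid initialization
        grids = np.meshgrid(*axes_mm, indexing="ij")
        pts = np.stack(grids, axis=-1) + fixed.origin
        base = init.apply(pts.reshape(-1, 3)).reshape(pts.shape)

        o_m, org_m, sp_m = moving.orientation, moving.origin, moving.spacing
        n_vox = fdata.size

        def cost_and_grad(theta):
            c = theta.reshape(coeffs.shape)
            disp = model.evaluate(weights, c)
            idx = (base + disp - org_m) @ o_m / sp_m
            warped = _sample(mov_level, idx, order=1, cval=fill)
            r = warped - fdata
            mse = float(np.mean(r * r))
            if not np.isfinite(mse):
                raise OptimizationError(
                    f"non-finite cost at pyramid level {level}"
                )
            g_world = np.empty(shape + (3,))
            for a in range(3):
                g_world[..., a] = _sample(grad_axes[a], idx, order=1, cval=0.0)
            g_world = g_world @ o_m.T  # moving-axis gradients -> world mm
            g_dense = (2.0 / n_vox) * r[..., None] * g_world
            g_coef = model.adjoint(weights, g_dense)
            be, g_be = model.bending_energy(c)
            return mse + lam * be, (g_coef + lam * g_be).ravel()

        res = minimize(
            cost_and_grad, coeffs.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-7},
        )
        coeffs = res.x.reshape(coeffs.shape)
        log.info("registration level %d (factor %d): cost %.6g after %d iters",
                 level, factor, res.fun, res.nit)

    # final full-resolution field; guard against regressions vs rigid-only
    axes_mm = [np.arange(n) * s for n, s in zip(fixed.shape, fixed.spacing)]
    weights = model.weights_for(axes_mm)
    grids = np.meshgrid(*axes_mm, indexing="ij")
    pts = np.stack(grids, axis=-1) + fixed.origin
    base = init.apply(pts.reshape(-1, 3)).reshape(pts.shape)

    def full_mse(disp):
        idx = (base + disp - moving.origin) @ moving.orientation / moving.spacing
        warped = _sample(mov64, idx, order=1, cval=fill)
        return float(np.mean((warped - fixed.data) ** 2))

    disp_spline = model.evaluate(weights, coeffs)
    zero = np.zeros(fixed.shape + (3,))
    mse_rigid = full_mse(zero)
    mse_final = full_mse(disp_spline)
    if mse_final > mse_rigid:
        log.warning("B-spline stage regressed MSE (%.4g > %.4g); "
                    "keeping rigid-only field", mse_final, mse_rigid)
        disp_spline = zero

    total = base - pts + disp_spline
    return DeformationField(total, fixed.spacing, fixed.origin, fixed.orientation)


# --------------------------------------------------------------------------
# Field application and I/O
# --------------------------------------------------------------------------

_INTERP_ORDER = {"linear": 1, "nearest": 0}


def apply_deformation(v: Volume, field: DeformationField,
                      interpolation: str = "linear",
                      fill: float | None = None) -> Volume:
    """Warp ``v`` onto the field's grid: out(x) = v(x + d(x))."""
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if fill is None:
        fill = modality_fill_value(v.modality_tag)
    shape = field.shape
    axes_mm = [np.arange(n) * s for n, s in zip(shape, field.spacing)]
    grids = np.meshgrid(*axes_mm, indexing="ij")
    pts = np.stack(grids, axis=-1) @ field.orientation.T + field.origin
    world = pts + field.displacements
    idx = (world - v.origin) @ v.orientation / v.spacing
    out = _sample(v.data.astype(np.float64), idx,
                  order=_INTERP_ORDER[interpolation], cval=fill)
    if v.modality_tag == "MASK":
        out = (out > 0.5).astype(np.uint8) if interpolation == "linear" else out.astype(np.uint8)
    return Volume(out, field.spacing, field.origin, field.orientation,
                  v.modality_tag)


def write_field(field: DeformationField, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = field.orientation * field.spacing[np.newaxis, :]
    affine[:3, 3] = field.origin
    img = nib.Nifti1Image(field.displacements.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_field(path) -> DeformationField:
    img = nib.load(str(path))
    affine = img.affine
    rzs = affine[:3, :3]
    spacing = np.linalg.norm(rzs, axis=0)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise GeometryError(f"{path} is not a 3-component displacement field")
    return DeformationField(data, spacing, affine[:3, 3], rzs / spacing)
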