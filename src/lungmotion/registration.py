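"""Mass-preserving non-rigid registration with the SSTVD cost.

The sum of squared tissue volume difference (SSTVD) compares *tissue volume*
rather than raw intensity: with v the voxel volume, β the tissue fraction of
the HU value (linear air/tissue mixing, HU clamped to [hu_air, hu_tissue])
and J the Jacobian determinant of the transform T(x) = x + u(x),

    cost(u) = Σ_x [ v·β_fixed(x) − v·J(x)·β_moving(T(x)) ]²  +  λ·bending(u)

which is invariant to the density drop that accompanies lung inflation and is
zero exactly when the tissue-volume maps agree on the evaluated region.  The
fixed image is the expiration scan, so the recovered field directly gives the
expiration→inspiration displacement vectors without inversion.

The transform is a multiresolution cubic B-spline free-form deformation: at
each pyramid level a control-point correction is optimized with L-BFGS-B
(analytic gradients, including the Jacobian term through the cofactor matrix)
on top of the upsampled field from the coarser level.  All evaluation is
dense and deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .densitometry import DEFAULT_DENSITY, DensityConfig
from .errors import FoldingFieldError
from .fields import AnalyticDeformation
from .volume import ImageVolume, LungSegmentation, world_axes, world_to_index


@dataclass(frozen=True)
class RegistrationConfig:
    """Hyper-parameters of the SSTVD B-spline registration.

    ``bspline_grid_spacing`` is the control-point spacing (mm) at the
    *coarsest* level; it halves at each finer level.  ``smoothness_weight``
    multiplies a squared-second-difference bending penalty on the control
    lattice.  ``seed`` is reserved for stochastic sampling variants; the
    default evaluation is full-grid and deterministic.
    """

    pyramid_levels: int = 3
    bspline_grid_spacing: float = 24.0
    min_control_spacing: float = 12.0
    max_iterations: int = 100
    coarse_iteration_scale: float = 2.0
    convergence_tol: float = 1e-6
    smoothness_weight: float = 1e-3
    density_config: DensityConfig = dc_field(default_factory=lambda: DEFAULT_DENSITY)
    mask_restriction: bool = True
    mask_dilation_mm: float = 12.0
    fold_retries: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be >= 0")

    def digest(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass(eq=False)
class DeformationField:
    """Dense per-voxel displacement u(x) (mm) on the expiration grid."""

    u: np.ndarray                       # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[3] != 3:
            raise ValueError("field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("field must be finite everywhere")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.u.shape[:3]

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        idx = world_to_index(pts, self.spacing, self.origin)
        if idx.min() < -1e-6 or (idx - (np.asarray(self.shape) - 1)).max() > 1e-6:
            raise ValueError("points outside the field domain")
        out = np.empty_like(pts)
        for d in range(3):
            out[..., d] = ndimage.map_coordinates(
                self.u[..., d], idx.reshape(-1, 3).T, order=1, mode="nearest"
            ).reshape(pts.shape[:-1])
        return out

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement_at(points)

    def jacobian_map(self) -> np.ndarray:
        return jacobian_det_map(self.u, self.spacing)

    @classmethod
    def from_analytic(
        cls, analytic: AnalyticDeformation, shape, spacing, origin=(0.0, 0.0, 0.0)
    ) -> "DeformationField":
        ax = world_axes(shape, spacing, origin)
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([xs, ys, zs], axis=-1)
        return cls(analytic.displacement(pts), spacing, origin)

    def save(self, path):
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.u.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path) -> "DeformationField":
        img = nib.load(str(path))
        affine = img.affine
        return cls(
            np.asarray(img.dataobj, dtype=float),
            tuple(np.abs(np.diag(affine)[:3])),
            tuple(affine[:3, 3]),
        )


# --------------------------------------------------------------------------- #
# Differential helpers

def _central_diff(arr, delta, axis):
    return np.gradient(arr, delta, axis=axis, edge_order=1)


def _central_diff_adjoint(s, delta, axis):
    """Exact adjoint of np.gradient's scheme (central interior, one-sided edges)."""
    sm = np.moveaxis(s, axis, 0)
    adj = np.zeros_like(sm)
    inner = sm[1:-1] / (2.0 * delta)
    adj[2:] += inner
    adj[:-2] -= inner
    adj[0] -= sm[0] / delta
    adj[1] += sm[0] / delta
    adj[-1] += sm[-1] / delta
    adj[-2] -= sm[-1] / delta
    return np.moveaxis(adj, 0, axis)


def _grad_tensor(u, spacing):
    """G[..., d, e] = δ_de + ∂u_d/∂x_e by central differences."""
    G = np.empty(u.shape[:3] + (3, 3))
    for d in range(3):
        for e in range(3):
            G[..., d, e] = _central_diff(u[..., d], spacing[e], axis=e)
        G[..., d, d] += 1.0
    return G


def _det3(G):
    return (
        G[..., 0, 0] * (G[..., 1, 1] * G[..., 2, 2] - G[..., 1, 2] * G[..., 2, 1])
        - G[..., 0, 1] * (G[..., 1, 0] * G[..., 2, 2] - G[..., 1, 2] * G[..., 2, 0])
        + G[..., 0, 2] * (G[..., 1, 0] * G[..., 2, 1] - G[..., 1, 1] * G[..., 2, 0])
    )


def _cofactor3(G):
    """cof[..., d, e] = ∂det(G)/∂G[..., d, e]."""
    c = np.empty_like(G)
    c[..., 0, 0] = G[..., 1, 1] * G[..., 2, 2] - G[..., 1, 2] * G[..., 2, 1]
    c[..., 0, 1] = -(G[..., 1, 0] * G[..., 2, 2] - G[..., 1, 2] * G[..., 2, 0])
    c[..., 0, 2] = G[..., 1, 0] * G[..., 2, 1] - G[..., 1, 1] * G[..., 2, 0]
    c[..., 1, 0] = -(G[..., 0, 1] * G[..., 2, 2] - G[..., 0, 2] * G[..., 2, 1])
    c[..., 1, 1] = G[..., 0, 0] * G[..., 2, 2] - G[..., 0, 2] * G[..., 2, 0]
    c[..., 1, 2] = -(G[..., 0, 0] * G[..., 2, 1] - G[..., 0, 1] * G[..., 2, 0])
    c[..., 2, 0] = G[..., 0, 1] * G[..., 1, 2] - G[..., 0, 2] * G[..., 1, 1]
    c[..., 2, 1] = -(G[..., 0, 0] * G[..., 1, 2] - G[..., 0, 2] * G[..., 1, 0])
    c[..., 2, 2] = G[..., 0, 0] * G[..., 1, 1] - G[..., 0, 1] * G[..., 1, 0]
    return c


def jacobian_det_map(u, spacing) -> np.ndarray:
    """Central-difference Jacobian determinant of T = id + u, per voxel."""
    return _det3(_grad_tensor(np.asarray(u, dtype=float), spacing))


def _trilinear_with_grad(vol, coords, spacing):
    """Trilinear interpolation with its exact spatial gradient.

    ``coords`` are fractional voxel indices of shape (3, N).  Out-of-domain
    coordinates are clamped (constant extension); the derivative along a
    clamped axis is exactly zero, so the returned gradient is the true
    derivative of the interpolant actually evaluated.
    """
    n = vol.shape
    c, clamped, base, frac = [], [], [], []
    for d in range(3):
        cd = np.clip(coords[d], 0.0, n[d] - 1.0)
        clamped.append((coords[d] < 0.0) | (coords[d] > n[d] - 1.0))
        bd = np.minimum(cd.astype(np.intp), n[d] - 2)
        c.append(cd)
        base.append(bd)
        frac.append(cd - bd)
    f0, f1, f2 = frac
    corners = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners[(di, dj, dk)] = vol[base[0] + di, base[1] + dj, base[2] + dk]

    def lerp(a, b, t):
        return a + (b - a) * t

    # collapse axis 2, then 1, then 0; keep partials along the way
    c00 = lerp(corners[0, 0, 0], corners[0, 0, 1], f2)
    c01 = lerp(corners[0, 1, 0], corners[0, 1, 1], f2)
    c10 = lerp(corners[1, 0, 0], corners[1, 0, 1], f2)
    c11 = lerp(corners[1, 1, 0], corners[1, 1, 1], f2)
    c0 = lerp(c00, c01, f1)
    c1 = lerp(c10, c11, f1)
    value = lerp(c0, c1, f0)

    d0 = c1 - c0
    d1 = lerp(c01 - c00, c11 - c10, f0)
    dz00 = corners[0, 0, 1] - corners[0, 0, 0]
    dz01 = corners[0, 1, 1] - corners[0, 1, 0]
    dz10 = corners[1, 0, 1] - corners[1, 0, 0]
    dz11 = corners[1, 1, 1] - corners[1, 1, 0]
    d2 = lerp(lerp(dz00, dz01, f1), lerp(dz10, dz11, f1), f0)

    grads = []
    for d, dd in enumerate((d0, d1, d2)):
        g = dd / spacing[d]
        g[clamped[d]] = 0.0
        grads.append(g)
    return value, grads


def sstvd_voxel_term(voxel_volume, beta_fixed, beta_moving_warped, jacobian):
    """Squared tissue-volume difference contributed by one evaluated voxel."""
    return (
        voxel_volume * beta_fixed - voxel_volume * jacobian * beta_moving_warped
    ) ** 2


# --------------------------------------------------------------------------- #
# Cubic B-spline lattice

def _b3(t):
    at = np.abs(t)
    out = np.zeros_like(at)
    near = at < 1.0
    far = (at >= 1.0) & (at < 2.0)
    out[near] = (4.0 - 6.0 * at[near] ** 2 + 3.0 * at[near] ** 3) / 6.0
    out[far] = (2.0 - at[far]) ** 3 / 6.0
    return out


def _basis_1d(coords_mm: np.ndarray, ctrl_spacing: float):
    """Dense basis matrix B[p, i] = B3(x_p/δ − i) over the needed index range."""
    t = np.asarray(coords_mm, dtype=float) / ctrl_spacing
    base = np.floor(t).astype(int)
    imin = base.min() - 1
    imax = base.max() + 2
    nc = imax - imin + 1
    B = np.zeros((t.size, nc))
    rows = np.arange(t.size)
    for k in range(-1, 3):
        idx = base + k
        B[rows, idx - imin] = _b3(t - idx)
    return B


def _dense_from_coeffs(C, Bx, By, Bz):
    t = np.tensordot(Bx, C, axes=(1, 0))      # (nx, ncy, ncz, 3)
    t = np.tensordot(By, t, axes=(1, 1))      # (ny, nx, ncz, 3)
    t = np.tensordot(Bz, t, axes=(1, 2))      # (nz, ny, nx, 3)
    return np.transpose(t, (2, 1, 0, 3))


def _coeff_adjoint(G, Bx, By, Bz):
    t = np.tensordot(Bx, G, axes=(0, 0))      # (ncx, ny, nz, 3)
    t = np.tensordot(By, t, axes=(0, 1))      # (ncy, ncx, nz, 3)
    t = np.tensordot(Bz, t, axes=(0, 2))      # (ncz, ncy, ncx, 3)
    return np.transpose(t, (2, 1, 0, 3))


def _bending(C):
    """Squared second differences of the control lattice, with gradient."""
    be = 0.0
    grad = np.zeros_like(C)
    for axis in range(3):
        Cm = np.moveaxis(C, axis, 0)
        gm = np.moveaxis(grad, axis, 0)
        if Cm.shape[0] < 3:
            continue
        d2 = Cm[2:] - 2.0 * Cm[1:-1] + Cm[:-2]
        be += float((d2**2).sum())
        gm[2:] += 2.0 * d2
        gm[1:-1] -= 4.0 * d2
        gm[:-2] += 2.0 * d2
    return be, grad


# --------------------------------------------------------------------------- #
# Per-level SSTVD problem

class _LevelProblem:
    def __init__(self, beta_f, beta_m, weight, spacing, u0, ctrl_spacing, smooth_w):
        self.beta_f = beta_f
        self.beta_m = beta_m
        self.weight = weight.astype(float)
        self.spacing = spacing
        self.u0 = u0
        self.smooth_w = smooth_w
        self.vox_vol = float(np.prod(spacing))
        shape = beta_f.shape
        ax = world_axes(shape, spacing, (0.0, 0.0, 0.0))
        self.Bx = _basis_1d(ax[0], ctrl_spacing)
        self.By = _basis_1d(ax[1], ctrl_spacing)
        self.Bz = _basis_1d(ax[2], ctrl_spacing)
        self.n_coeffs = (self.Bx.shape[1], self.By.shape[1], self.Bz.shape[1], 3)
        ix, iy, iz = np.meshgrid(
            *[np.arange(n, dtype=float) for n in shape], indexing="ij"
        )
        self.base_idx = (ix, iy, iz)

    def coeffs(self, flat):
        return flat.reshape(self.n_coeffs)

    def dense_field(self, flat):
        return self.u0 + _dense_from_coeffs(self.coeffs(flat), self.Bx, self.By, self.Bz)

    def cost_grad(self, flat):
        u = self.dense_field(flat)
        coords = np.stack(
            [self.base_idx[d] + u[..., d] / self.spacing[d] for d in range(3)]
        )
        flat_coords = coords.reshape(3, -1)
        bm_flat, gm_flat = _trilinear_with_grad(self.beta_m, flat_coords, self.spacing)
        bm = bm_flat.reshape(self.beta_f.shape)
        G = _grad_tensor(u, self.spacing)
        J = _det3(G)
        v = self.vox_vol
        r = self.weight * v * (self.beta_f - J * bm)
        data = float((r * r).sum())

        grad_dense = np.empty_like(u)
        grad_bm = -2.0 * v * J * r
        for d in range(3):
            grad_dense[..., d] = grad_bm * gm_flat[d].reshape(self.beta_f.shape)
        q = -2.0 * v * bm * r
        cof = _cofactor3(G)
        for d in range(3):
            acc = np.zeros(self.beta_f.shape)
            for e in range(3):
                acc += _central_diff_adjoint(q * cof[..., d, e], self.spacing[e], e)
            grad_dense[..., d] += acc

        grad_c = _coeff_adjoint(grad_dense, self.Bx, self.By, self.Bz)
        cost = data
        if self.smooth_w > 0:
            be, gbe = _bending(self.coeffs(flat))
            cost += self.smooth_w * be
            grad_c = grad_c + self.smooth_w * gbe
        return cost, grad_c.ravel()


# --------------------------------------------------------------------------- #
# Public cost

def _weight_mask(fixed, fixed_seg, config) -> np.ndarray:
    if not config.mask_restriction or fixed_seg is None:
        return np.ones(fixed.shape)
    if isinstance(fixed_seg, LungSegmentation):
        mask = fixed_seg.lung_mask()
    else:
        mask = np.asarray(fixed_seg, dtype=bool)
    it = int(round(config.mask_dilation_mm / min(fixed.spacing)))
    if it <= 0:
        return mask.astype(float)
    return ndimage.binary_dilation(mask, iterations=it).astype(float)


def _beta(volume: ImageVolume, density: DensityConfig) -> np.ndarray:
    hu = np.clip(volume.values, density.hu_air, density.hu_tissue)
    return (hu - density.hu_air) / (density.hu_tissue - density.hu_air)


def sstvd_cost(
    fixed: ImageVolume,
    moving: ImageVolume,
    field: DeformationField,
    config: RegistrationConfig | None = None,
    fixed_seg=None,
    return_parts: bool = False,
):
    """SSTVD cost of a given field on the fixed (expiration) grid.

    Raises :class:`FoldingFieldError` before evaluation if the transform has a
    non-positive Jacobian on the evaluated region, and ``ValueError`` on a
    field/volume domain mismatch.
    """
    cfg = config or RegistrationConfig()
    if field.u.shape[:3] != fixed.shape:
        raise ValueError("field domain does not match the fixed volume")
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving volumes must share a grid")
    weight = _weight_mask(fixed, fixed_seg, cfg)
    J = jacobian_det_map(field.u, fixed.spacing)
    if np.any(J[weight > 0] <= 0):
        raise FoldingFieldError("non-positive Jacobian on the evaluated region")
    beta_f = _beta(fixed, cfg.density_config)
    beta_m = _beta(moving, cfg.density_config)
    ax = [np.arange(n, dtype=float) for n in fixed.shape]
    ix, iy, iz = np.meshgrid(*ax, indexing="ij")
    coords = np.stack(
        [
            ix + field.u[..., 0] / fixed.spacing[0],
            iy + field.u[..., 1] / fixed.spacing[1],
            iz + field.u[..., 2] / fixed.spacing[2],
        ]
    ).reshape(3, -1)
    bm = ndimage.map_coordinates(beta_m, coords, order=1, mode="nearest").reshape(
        fixed.shape
    )
    v = fixed.voxel_volume_mm3
    data = float(
        (weight * sstvd_voxel_term(v, beta_f, bm, J)).sum()
    )
    be = 0.0
    if cfg.smoothness_weight > 0:
        for axis in range(3):
            um = np.moveaxis(field.u, axis, 0)
            d2 = um[2:] - 2.0 * um[1:-1] + um[:-2]
            be += float((d2**2).sum())
    cost = data + cfg.smoothness_weight * be
    if return_parts:
        return cost, {"data": data, "bending": be}
    return cost


# --------------------------------------------------------------------------- #
# Registration driver

def _resize(vol: np.ndarray, shape) -> np.ndarray:
    if vol.shape == tuple(shape):
        return vol
    coords = np.meshgrid(
        *[np.linspace(0.0, vol.shape[a] - 1.0, shape[a]) for a in range(3)],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        vol, np.stack(coords).reshape(3, -1), order=1, mode="nearest"
    ).reshape(shape)


def _downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol, sigma=factor / 2.0)
    shape = tuple(int(np.ceil(n / factor)) for n in vol.shape)
    return _resize(sm, shape)


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_seg=None,
    config: RegistrationConfig | None = None,
) -> DeformationField:
    """Multiresolution SSTVD B-spline registration (fixed = expiration).

    Returns the dense expiration→inspiration displacement field on the fixed
    grid.  The per-level cost trace (monotone non-increasing accepted values),
    convergence flags and a config digest are recorded in ``provenance``.
    If a level produces Jacobian folding inside the evaluation mask, the level
    is re-run with a 10× stronger bending penalty (up to ``fold_retries``
    times); a final folded field raises :class:`FoldingFieldError`.
    """
    cfg = config or RegistrationConfig()
    if fixed.shape != moving.shape or fixed.spacing != moving.spacing:
        raise ValueError("fixed and moving volumes must share grid and spacing")
    beta_f = _beta(fixed, cfg.density_config)
    beta_m = _beta(moving, cfg.density_config)
    weight = _weight_mask(fixed, fixed_seg, cfg)

    factors = [2 ** (cfg.pyramid_levels - 1 - i) for i in range(cfg.pyramid_levels)]
    u = None
    traces = []
    converged = []
    smooth_used = []
    for li, f in enumerate(factors):
        bf_l = _downsample(beta_f, f)
        bm_l = _downsample(beta_m, f)
        w_l = (_downsample(weight, f) > 0.25).astype(float)
        spacing_l = tuple(s * f for s in fixed.spacing)
        shape_l = bf_l.shape
        if u is None:
            u0 = np.zeros(shape_l + (3,))
        else:
            u0 = np.stack([_resize(u[..., d], shape_l) for d in range(3)], axis=-1)
        ctrl = max(cfg.bspline_grid_spacing / (2**li), cfg.min_control_spacing)
        level_iters = int(
            round(cfg.max_iterations * cfg.coarse_iteration_scale ** (len(factors) - 1 - li))
        )
        lam = cfg.smoothness_weight
        for attempt in range(cfg.fold_retries + 1):
            prob = _LevelProblem(bf_l, bm_l, w_l, spacing_l, u0, ctrl, lam)
            x0 = np.zeros(int(np.prod(prob.n_coeffs)))
            trace = []
            best = {"f": np.inf}

            def fun(x, _prob=prob, _best=best):
                c, g = _prob.cost_grad(x)
                if c < _best["f"]:
                    _best["f"] = c
                return c, g

            res = minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={
                    "maxiter": level_iters,
                    "ftol": cfg.convergence_tol,
                    "gtol": 1e-12,
                },
                callback=lambda xk, _t=trace, _b=best: _t.append(_b["f"]),
            )
            u_l = prob.dense_field(res.x)
            J = jacobian_det_map(u_l, spacing_l)
            if np.all(J[w_l > 0] > 0):
                break
            lam = max(lam, 1e-6) * 10.0
        traces.append(trace)
        converged.append(bool(res.success))
        smooth_used.append(lam)
        u = u_l

    J = jacobian_det_map(u, fixed.spacing)
    if np.any(J[weight > 0] <= 0):
        raise FoldingFieldError("registration produced a folding field in the lung")
    return DeformationField(
        u,
        fixed.spacing,
        fixed.origin,
        provenance={
            "config": cfg.digest(),
            "cost_trace": traces,
            "converged": converged,
            "smoothness_used": smooth_used,
        },
    )


def landmark_error(field, exp_points, insp_points) -> dict:
    """Euclidean distances between T(expiration landmarks) and their
    inspiration positions; returns mean/max and per-point distances (mm)."""
    exp_points = np.asarray(exp_points, dtype=float)
    insp_points = np.asarray(insp_points, dtype=float)
    if isinstance(field, AnalyticDeformation):
        mapped = field.transform(exp_points)
    else:
        mapped = field.transform_points(exp_points)
    d = np.linalg.norm(mapped - insp_points, axis=-1)
    return {"mean": float(d.mean()), "max": float(d.max()), "distances": d}
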