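"""Synthetic thoracic phantoms with analytically known breathing deformation.

The phantom emulates a paired full-expiration / full-inspiration thoracic CT
acquisition: two half-ellipsoid lungs sit above a spherical-cap diaphragm
dome, embedded in soft tissue.  The expiration volume is built from the
continuum model; the inspiration volume is the *mass-preserving* warp of the
expiration volume under a closed-form dome-descent field (tissue fraction
divides by the local Jacobian determinant, so local tissue mass is conserved
— exactly the assumption the SSTVD registration cost exploits).  Lobe label
maps are advected with the same field, so both segmentations describe the
same material region.

Everything is deterministic for a fixed seed: parenchymal texture, lesion
placement and scanner noise each draw from independent child generators of
the spec seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .densitometry import (
    DEFAULT_DENSITY,
    DensityConfig,
    percent_laa,
    tissue_fraction,
)
from .errors import FoldingFieldError, GeometryOverflowError, LesionOverflowError
from .fields import AnalyticDeformation, TaperedDomeField
from .volume import ImageVolume, LungSegmentation, LOBE_CODES, world_axes, world_to_index


# --------------------------------------------------------------------------- #
# Specification

@dataclass(frozen=True)
class LungGeometry:
    """One lung: ellipsoid centre and semi-axes (mm, patient frame)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass(frozen=True)
class LesionSpec:
    """Low-attenuation (emphysema-like) lesion burden.

    Either a fixed ``count`` of spherical blobs, or a ``target_laa_insp``
    percentage that the generator reaches iteratively (within ±2 percentage
    points).  ``lobes`` optionally restricts placement to named lobes.
    """

    count: int | None = None
    radius_mm: float = 7.0
    target_laa_insp: float = 0.0
    lobes: tuple[str, ...] | None = None
    hu: float = -980.0

    def __post_init__(self):
        if not (0.0 <= self.target_laa_insp <= 60.0):
            raise ValueError("target_laa_insp must be in [0, 60] percent")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.hu > -960.0:
            raise ValueError("lesion HU must be <= -960")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject.

    ``motion_amplitudes`` is (dx transverse, dy dorsal–ventral, dz apico-basal)
    in mm, expiration→inspiration; dome descent means dz < 0 and the default
    dy < 0 is ventral-directed, so xy-plane displacement angles cluster near
    180°, as observed on real diaphragms.  Under the default amplitudes
    |dz| >= |dy| >= |dx|, matching the normal-subject ordering of diaphragm
    motion (apico-basal dominant).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_geometry: dict | None = None
    dome_height: float = 20.0
    motion_amplitudes: tuple[float, float, float] = (0.5, -2.0, -10.0)
    background_hu: float = 40.0
    lung_hu_at_expiration: float = -850.0
    lesion_spec: LesionSpec = dc_field(default_factory=LesionSpec)
    noise_sd: float = 20.0
    texture_amplitude_hu: float = 60.0
    mask_margin_mm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        dx, dy, dz = self.motion_amplitudes
        if (dx, dy, dz) != (0.0, 0.0, 0.0) and dz >= 0:
            raise ValueError(
                "non-zero motion requires dome descent (dz < 0) so that "
                "inspiration inflates the lung"
            )
        geo = self.lungs()
        min_axis = min(min(g.semi_axes) for g in geo.values())
        if self.lesion_spec.radius_mm >= min_axis:
            raise ValueError("lesion radius must be smaller than the lung semi-axes")

    @property
    def segmentation_margin_mm(self) -> float:
        """Erosion of the label maps relative to the pleural HU boundary.

        Keeps the labelled lung clear of the partial-volume shell (at least
        one voxel, never below 2 mm), as clinical lobe segmentations do.
        """
        if self.mask_margin_mm is not None:
            return self.mask_margin_mm
        return max(2.0, max(self.spacing))

    def extent(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))

    def lungs(self) -> dict[str, LungGeometry]:
        """Lung geometry; defaults scale with the grid extent."""
        if self.lung_geometry is not None:
            return self.lung_geometry
        ex, ey, ez = self.extent()
        semi = (0.158 * ex, 0.274 * ey, 0.358 * ez)
        cy, cz = 0.5 * ey, 0.537 * ez
        off = 0.226 * ex
        return {
            "left": LungGeometry((0.5 * ex + off, cy, cz), semi),   # +x = patient-left
            "right": LungGeometry((0.5 * ex - off, cy, cz), semi),
        }

    def with_(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


# --------------------------------------------------------------------------- #
# Continuum model

class PhantomModel:
    """Continuum (grid-free) description of one phantom subject.

    All geometry lives in material (expiration) coordinates; the inspiration
    configuration is obtained by pushing material points through the truth
    field.  Oracle computations in tests integrate these continuum functions
    directly, independently of the voxelised pipeline.
    """

    def __init__(self, spec: PhantomSpec, density: DensityConfig = DEFAULT_DENSITY):
        self.spec = spec
        self.density = density
        self.lungs = spec.lungs()
        self.lesions: list[tuple[np.ndarray, float]] = []  # (centre mm, radius mm)

        tops = [g.center[2] + g.semi_axes[2] for g in self.lungs.values()]
        bases = [g.center[2] - g.semi_axes[2] for g in self.lungs.values()]
        self.z_top = max(tops)
        self.z_bottom = min(bases)
        self.field: AnalyticDeformation = TaperedDomeField(
            spec.motion_amplitudes, z_top=self.z_top, z_bottom=self.z_bottom
        )

        # Parenchymal texture: a smooth random field in material coordinates,
        # evaluated through a cubic spline so it is defined everywhere.
        ex = spec.extent()
        self._tex_spacing = max(ex) / 12.0
        ntex = [int(np.ceil(e / self._tex_spacing)) + 5 for e in ex]
        self._tex_origin = np.array([-2.0 * self._tex_spacing] * 3)
        rng_tex, self._rng_lesions, self._rng_noise = [
            np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
        ]
        coarse = rng_tex.standard_normal(tuple(ntex))
        self._tex_coeffs = ndimage.spline_filter(coarse, order=3)

    # -- geometry ----------------------------------------------------------- #

    def dome_surface_z(self, side: str, x, y):
        """Diaphragm dome height z(x, y) (mm) under the named lung.

        Spherical cap of height ``dome_height`` rising from the ellipsoid base
        plane; flat at the base plane outside the cap footprint.
        """
        g = self.lungs[side]
        h = self.spec.dome_height
        z_base = g.center[2] - g.semi_axes[2]
        r_cap = 1.15 * g.semi_axes[0]
        r_sph = (r_cap**2 + h**2) / (2.0 * h)
        rho2 = (np.asarray(x) - g.center[0]) ** 2 + (np.asarray(y) - g.center[1]) ** 2
        cap = np.sqrt(np.maximum(r_sph**2 - rho2, 0.0)) - (r_sph - h)
        return z_base + np.maximum(cap, 0.0)

    def lung_indicator(self, pts, side: str, margin: float = 0.0):
        """Boolean: material points inside the lung, eroded by ``margin`` mm."""
        g = self.lungs[side]
        pts = np.asarray(pts, dtype=float)
        semi = np.maximum(np.asarray(g.semi_axes) - margin, 1e-6)
        rel = (pts - np.asarray(g.center)) / semi
        inside = (rel**2).sum(axis=-1) <= 1.0
        dome = self.dome_surface_z(side, pts[..., 0], pts[..., 1])
        return inside & (pts[..., 2] >= dome + margin)

    def lobe_labels_at(self, pts, margin: float | None = None) -> np.ndarray:
        """Lobe label codes at material points (0 = non-lung).

        Lobes are z-bands of each lung: LUL/LLL split at the lung centre;
        RUL / RML / RLL split at centre + 0.3 * semi_z and the centre.
        """
        if margin is None:
            margin = self.spec.segmentation_margin_mm
        pts = np.asarray(pts, dtype=float)
        out = np.zeros(pts.shape[:-1], dtype=np.int16)
        z = pts[..., 2]
        left = self.lung_indicator(pts, "left", margin)
        gl = self.lungs["left"]
        out[left & (z >= gl.center[2])] = LOBE_CODES["LUL"]
        out[left & (z < gl.center[2])] = LOBE_CODES["LLL"]
        right = self.lung_indicator(pts, "right", margin)
        gr = self.lungs["right"]
        z_rul = gr.center[2] + 0.3 * gr.semi_axes[2]
        out[right & (z >= z_rul)] = LOBE_CODES["RUL"]
        out[right & (z < z_rul) & (z >= gr.center[2])] = LOBE_CODES["RML"]
        out[right & (z < gr.center[2])] = LOBE_CODES["RLL"]
        return out

    # -- attenuation -------------------------------------------------------- #

    def texture(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        idx = (pts - self._tex_origin) / self._tex_spacing
        flat = idx.reshape(-1, 3).T
        vals = ndimage.map_coordinates(
            self._tex_coeffs, flat, order=3, prefilter=False, mode="nearest"
        )
        return vals.reshape(pts.shape[:-1])

    def hu_material(self, pts, include_lesions: bool = True) -> np.ndarray:
        """Noise-free expiration HU at material points."""
        pts = np.asarray(pts, dtype=float)
        hu = np.full(pts.shape[:-1], self.spec.background_hu, dtype=float)
        in_lung = self.lung_indicator(pts, "left") | self.lung_indicator(pts, "right")
        if in_lung.any():
            tex = np.abs(self.texture(pts[in_lung]))
            hu[in_lung] = (
                self.spec.lung_hu_at_expiration + self.spec.texture_amplitude_hu * tex
            )
        if include_lesions:
            for centre, radius in self.lesions:
                d2 = ((pts - centre) ** 2).sum(axis=-1)
                hu = np.where(d2 <= radius**2, self.spec.lesion_spec.hu, hu)
        return hu

    def beta_material(self, pts, include_lesions: bool = True) -> np.ndarray:
        return tissue_fraction(self.hu_material(pts, include_lesions), self.density)


# --------------------------------------------------------------------------- #
# Pair container

@dataclass(eq=False)
class PhantomPair:
    """One synthetic subject: paired scans, segmentations and the truth field."""

    expiration: ImageVolume
    inspiration: ImageVolume
    expiration_seg: LungSegmentation
    inspiration_seg: LungSegmentation
    truth: AnalyticDeformation
    spec: PhantomSpec
    model: PhantomModel | None = None


# --------------------------------------------------------------------------- #
# Mass-preserving warp (generic operation)

def _grid_points(shape, spacing, origin):
    ax = world_axes(shape, spacing, origin)
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    return np.stack([xs, ys, zs], axis=-1)


def warp_mass_preserving(
    volume: ImageVolume,
    field: AnalyticDeformation,
    density: DensityConfig = DEFAULT_DENSITY,
) -> ImageVolume:
    """Warp a volume under T = id + u so local tissue volume is conserved.

    The output value at grid point y is derived from the tissue fraction at
    the material point x = T⁻¹(y), divided by the Jacobian determinant J(x):
    a region expanded by a factor J keeps its tissue mass, so its tissue
    *fraction* drops by 1/J.  Interpolation of the source tissue-fraction map
    is trilinear.

    Raises
    ------
    FoldingFieldError
        If the field has a non-positive Jacobian determinant anywhere on the
        output grid.
    """
    pts = _grid_points(volume.shape, volume.spacing, volume.origin)
    x = field.invert(pts)
    j = field.jacobian_det(x)
    if np.any(j <= 0):
        raise FoldingFieldError("folding field: non-positive Jacobian determinant")
    hu = _warp_hu(volume.values, x, j, volume.spacing, volume.origin, density)
    return ImageVolume(hu, volume.spacing, volume.origin)


def _warp_hu(values, material_pts, jac, spacing, origin, density):
    beta = tissue_fraction(values, density)
    idx = world_to_index(material_pts, spacing, origin)
    beta_x = ndimage.map_coordinates(
        beta, idx.reshape(-1, 3).T, order=1, mode="nearest"
    ).reshape(values.shape)
    beta_new = np.clip(beta_x / jac, 0.0, 1.0)
    return density.hu_air + beta_new * (density.hu_tissue - density.hu_air)


# --------------------------------------------------------------------------- #
# Builder

_SUPERSAMPLE = 2


def _build_expiration_hu(model: PhantomModel) -> np.ndarray:
    """Antialiased expiration HU: 2x supersampling then block averaging."""
    spec = model.spec
    f = _SUPERSAMPLE
    shape = tuple(n * f for n in spec.grid_shape)
    fine_spacing = tuple(s / f for s in spec.spacing)
    fine_origin = tuple(-s / (2 * f) * (f - 1) for s in spec.spacing)
    pts = _grid_points(shape, fine_spacing, fine_origin)
    hu = model.hu_material(pts, include_lesions=False)
    nx, ny, nz = spec.grid_shape
    return hu.reshape(nx, f, ny, f, nz, f).mean(axis=(1, 3, 5))


def _check_geometry(model: PhantomModel, exp_labels: np.ndarray, spec: PhantomSpec):
    pts = _grid_points(spec.grid_shape, spec.spacing, (0.0, 0.0, 0.0))
    lung_pts = pts[exp_labels > 0]
    if lung_pts.size == 0:
        raise GeometryOverflowError("lung geometry does not intersect the grid")
    warped = model.field.transform(lung_pts[:: max(1, lung_pts.shape[0] // 5000)])
    hi = np.array(spec.extent())
    if np.any(warped < -0.5 * np.array(spec.spacing)) or np.any(
        warped > hi + 0.5 * np.array(spec.spacing)
    ):
        raise GeometryOverflowError("motion pushes the lung outside the grid")


def _carve_lesions(hu: np.ndarray, model: PhantomModel, spacing):
    """Stamp spherical lesions into a voxelised expiration HU map, in place."""
    spec = model.spec
    for centre, radius in model.lesions:
        lo = np.maximum(np.floor((centre - radius) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((centre + radius) / spacing).astype(int) + 1, hu.shape
        )
        if np.any(lo >= hi):
            continue
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        ax = [spacing[a] * np.arange(lo[a], hi[a]) for a in range(3)]
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        d2 = (xs - centre[0]) ** 2 + (ys - centre[1]) ** 2 + (zs - centre[2]) ** 2
        region = hu[sub]
        hu[sub] = np.where(d2 <= radius**2, spec.lesion_spec.hu, region)


def _sample_lesion_centres(model: PhantomModel, n_pool: int) -> np.ndarray:
    """Seeded pool of admissible lesion centres (sphere fully inside a lung)."""
    spec = model.spec
    rng = model._rng_lesions
    radius = spec.lesion_spec.radius_mm
    allowed = spec.lesion_spec.lobes
    allowed_codes = (
        None if allowed is None else [LOBE_CODES[n] for n in allowed]
    )
    lo = np.zeros(3)
    hi = np.array(spec.extent())
    out = []
    attempts = 0
    while len(out) < n_pool and attempts < 200:
        cand = rng.uniform(lo, hi, size=(4096, 3))
        ok = model.lung_indicator(cand, "left", margin=radius) | model.lung_indicator(
            cand, "right", margin=radius
        )
        if allowed_codes is not None:
            ok &= np.isin(model.lobe_labels_at(cand, margin=0.0), allowed_codes)
        out.append(cand[ok])
        attempts += 1
    pool = np.concatenate(out) if out else np.empty((0, 3))
    return pool[:n_pool]


def build_phantom(
    spec: PhantomSpec, density: DensityConfig = DEFAULT_DENSITY
) -> PhantomPair:
    """Generate a paired expiration/inspiration phantom from a spec.

    Deterministic for a fixed seed.  The inspiration volume is the
    mass-preserving warp of the expiration volume under the analytic
    dome-descent field; label maps are advected with the same field.
    """
    model = PhantomModel(spec, density)
    pts = _grid_points(spec.grid_shape, spec.spacing, (0.0, 0.0, 0.0))
    exp_labels = model.lobe_labels_at(pts)
    _check_geometry(model, exp_labels, spec)

    exp_hu = _build_expiration_hu(model)

    identity_motion = spec.motion_amplitudes == (0.0, 0.0, 0.0)
    if identity_motion:
        inv_pts, jac = pts, np.ones(spec.grid_shape)
        insp_labels = exp_labels
    else:
        inv_pts = model.field.invert(pts)
        jac = model.field.jacobian_det(inv_pts)
        if np.any(jac <= 0):
            raise FoldingFieldError("phantom field folds on the grid")
        insp_labels = model.lobe_labels_at(inv_pts)

    noise_rng = model._rng_noise
    noise_exp = (
        noise_rng.standard_normal(spec.grid_shape) * spec.noise_sd
        if spec.noise_sd > 0
        else 0.0
    )
    noise_insp = (
        noise_rng.standard_normal(spec.grid_shape) * spec.noise_sd
        if spec.noise_sd > 0
        else 0.0
    )

    def assemble(exp_hu_lesioned):
        if identity_motion:
            insp_hu = exp_hu_lesioned.copy()
        else:
            insp_hu = _warp_hu(
                exp_hu_lesioned, inv_pts, jac, spec.spacing, (0.0, 0.0, 0.0), density
            )
        e = np.clip(exp_hu_lesioned + noise_exp, -1024.0, 3071.0)
        i = np.clip(insp_hu + noise_insp, -1024.0, 3071.0)
        return e, i

    lesion = spec.lesion_spec
    if lesion.count is None and lesion.target_laa_insp <= 0.0:
        exp_final, insp_final = assemble(exp_hu)
    elif lesion.count is not None:
        pool = _sample_lesion_centres(model, lesion.count)
        if pool.shape[0] < lesion.count:
            raise LesionOverflowError("cannot place the requested lesion count")
        model.lesions = [(pool[i], lesion.radius_mm) for i in range(lesion.count)]
        hu = exp_hu.copy()
        _carve_lesions(hu, model, np.array(spec.spacing))
        exp_final, insp_final = assemble(hu)
    else:
        exp_final, insp_final = _reach_laa_target(
            model, exp_hu, assemble, insp_labels, spec, density
        )

    sp, orig = spec.spacing, (0.0, 0.0, 0.0)
    return PhantomPair(
        expiration=ImageVolume(exp_final, sp, orig),
        inspiration=ImageVolume(insp_final, sp, orig),
        expiration_seg=LungSegmentation(exp_labels, sp, orig),
        inspiration_seg=LungSegmentation(insp_labels, sp, orig),
        truth=model.field,
        spec=spec,
        model=model,
    )


def _reach_laa_target(model, exp_hu, assemble, insp_labels, spec, density):
    """Add lesions until inspiration %LAA_insp is within ±2 pp of target."""
    lesion = spec.lesion_spec
    target = lesion.target_laa_insp
    insp_mask = insp_labels > 0
    lung_mm3 = insp_mask.sum() * float(np.prod(spec.spacing))
    lesion_mm3 = 4.0 / 3.0 * np.pi * lesion.radius_mm**3
    if target > 60.0 or target / 100.0 * lung_mm3 > 0.6 * lung_mm3:
        raise LesionOverflowError("%LAA target not reachable inside the lung")

    n_pool = int(np.ceil(4.0 * target / 100.0 * lung_mm3 / lesion_mm3)) + 32
    pool = _sample_lesion_centres(model, n_pool)

    n = max(1, int(round(target / 100.0 * lung_mm3 / lesion_mm3)))
    spacing = np.array(spec.spacing)
    best = None
    for _ in range(10):
        if n > pool.shape[0]:
            raise LesionOverflowError("lesion pool exhausted before reaching target")
        model.lesions = [(pool[i], lesion.radius_mm) for i in range(n)]
        hu = exp_hu.copy()
        _carve_lesions(hu, model, spacing)
        exp_final, insp_final = assemble(hu)
        vol = ImageVolume(insp_final, spec.spacing)
        measured = percent_laa(vol, insp_mask, density.laa_insp_threshold)
        best = (exp_final, insp_final)
        if abs(measured - target) <= 1.0:
            break
        if measured <= 0.05:
            n = n * 2
        else:
            n = max(1, int(round(n * target / measured)))
    else:
        if abs(measured - target) > 2.0:
            raise LesionOverflowError(
                f"could not reach %LAA target {target} (got {measured:.2f})"
            )
    return best


def seed_emphysema(
    pair: PhantomPair,
    lesion_spec: LesionSpec,
    seed: int,
    density: DensityConfig = DEFAULT_DENSITY,
) -> PhantomPair:
    """Re-generate a pair with the given lesion burden (deformation-linked).

    Lesions are stamped in material (expiration) coordinates and re-warped, so
    each blob appears at corresponding locations in both volumes.  A zero
    target returns an identically re-built pair (no lesions).
    """
    spec = pair.spec.with_(lesion_spec=lesion_spec, seed=seed)
    if lesion_spec.count is None and lesion_spec.target_laa_insp <= 0.0:
        return pair
    return build_phantom(spec, density)


def shipped_specs() -> dict[str, PhantomSpec]:
    """The named phantom configurations the package ships and validates."""
    return {
        "default": PhantomSpec(),
        "shallow": PhantomSpec(motion_amplitudes=(0.25, -1.0, -5.0), seed=5),
        "emphysematous": PhantomSpec(
            grid_shape=(64, 64, 64),
            spacing=(3.0, 3.0, 3.0),
            lesion_spec=LesionSpec(target_laa_insp=15.0),
            seed=2,
        ),
    }


# --------------------------------------------------------------------------- #
# Group-structured synthetic cohorts

#: Whole-diaphragm normalized-metric means used as group defaults
#: (displacement metrics are dimensionless: cm over (ΔV litres)^(1/3);
#: angles in degrees).  Per-subject dispersion is not identifiable from
#: published group means, so the SDs below are configurable study conditions,
#: not measurements.
_GROUP_METRIC_MEANS = {
    "normal": {
        "s3d": 3.50, "s2d": 1.18, "transverse": 0.12, "apicobasal": 3.17,
        "dorsoventral": 1.17, "angle_mean": 189.54, "angle_sd": 27.28,
    },
    "emphysema": {
        "s3d": 2.79, "s2d": 1.00, "transverse": 0.00, "apicobasal": 2.40,
        "dorsoventral": 0.99, "angle_mean": 186.72, "angle_sd": 37.51,
    },
    "IPF": {
        "s3d": 2.72, "s2d": 0.72, "transverse": 0.09, "apicobasal": 2.47,
        "dorsoventral": 0.71, "angle_mean": 192.09, "angle_sd": 48.31,
    },
}

_DEFAULT_METRIC_SDS = {
    "s3d": 1.0, "s2d": 0.5, "transverse": 0.2, "apicobasal": 1.0,
    "dorsoventral": 0.5, "angle_mean": 10.0, "angle_sd": 8.0,
}


@dataclass
class GroupSpec:
    """Distributional description of one synthetic subject group.

    ``laa_slopes`` couples a motion metric to %LAA_exp:
    metric = mean + slope * (laa_exp − laa_exp_mean) + residual noise, with
    the residual SD shrunk so the metric's total SD stays as configured; the
    implied generating correlation is slope * laa_exp_sd / metric_sd.
    """

    name: str
    n: int = 30
    metric_means: dict = dc_field(default_factory=dict)
    metric_sds: dict = dc_field(default_factory=dict)
    laa_insp_mean: float = 3.0
    laa_insp_sd: float = 1.5
    laa_exp_mean: float = 8.0
    laa_exp_sd: float = 4.0
    laa_slopes: dict = dc_field(default_factory=dict)
    edi_upper_fraction: float = 0.0
    volume_ratio_mean: float = 0.62
    volume_ratio_sd: float = 0.08
    insp_air_mean_l: float = 4.0
    insp_air_sd_l: float = 0.7
    pft_means: dict | None = None
    pft_sds: dict | None = None

    def __post_init__(self):
        means = dict(_GROUP_METRIC_MEANS.get(self.name, _GROUP_METRIC_MEANS["normal"]))
        means.update(self.metric_means)
        self.metric_means = means
        sds = dict(_DEFAULT_METRIC_SDS)
        sds.update(self.metric_sds)
        self.metric_sds = sds
        bad = [k for k, v in self.metric_sds.items() if v <= 0]
        if bad or self.laa_insp_sd <= 0 or self.laa_exp_sd <= 0:
            raise ValueError(f"invalid group spec: non-positive SD ({bad})")

    def implied_laa_correlation(self, metric: str) -> float:
        slope = self.laa_slopes.get(metric, 0.0)
        return slope * self.laa_exp_sd / self.metric_sds[metric]


def default_group_specs() -> dict[str, "GroupSpec"]:
    """Three groups with the canonical whole-diaphragm metric means and an
    emphysema %LAA_exp coupling that induces the characteristic negative
    correlation with 3D / apico-basal displacement."""
    return {
        "normal": GroupSpec(
            name="normal", n=29,
            laa_insp_mean=2.0, laa_insp_sd=1.0, laa_exp_mean=8.0, laa_exp_sd=4.0,
            pft_means={"fev1_pp": 95.0, "fvc_pp": 95.0, "fev1_fvc": 80.0,
                       "post_fvc_pp": 96.0},
            pft_sds={"fev1_pp": 10.0, "fvc_pp": 10.0, "fev1_fvc": 5.0,
                     "post_fvc_pp": 10.0},
        ),
        "emphysema": GroupSpec(
            name="emphysema", n=50,
            laa_insp_mean=25.0, laa_insp_sd=8.0, laa_exp_mean=30.0, laa_exp_sd=12.0,
            laa_slopes={"s3d": -0.546 / 12.0, "apicobasal": -0.521 / 12.0,
                        "dorsoventral": -0.387 / 24.0},
            edi_upper_fraction=0.46,
            pft_means={"fev1_pp": 55.0, "fvc_pp": 75.0, "fev1_fvc": 45.0,
                       "post_fvc_pp": 78.0},
            pft_sds={"fev1_pp": 15.0, "fvc_pp": 12.0, "fev1_fvc": 10.0,
                     "post_fvc_pp": 12.0},
        ),
        "IPF": GroupSpec(
            name="IPF", n=51,
            laa_insp_mean=3.0, laa_insp_sd=1.5, laa_exp_mean=10.0, laa_exp_sd=5.0,
            pft_means={"fev1_pp": 72.0, "fvc_pp": 65.0, "fev1_fvc": 85.0,
                       "post_fvc_pp": 68.0},
            pft_sds={"fev1_pp": 15.0, "fvc_pp": 15.0, "fev1_fvc": 5.0,
                     "post_fvc_pp": 15.0},
        ),
    }


def _fast_subject(spec: "GroupSpec", rng: np.random.Generator, subject_id: str):
    from .cohort import SubjectRecord
    from .densitometry import DensitometrySummary, classify_edi
    from .motionography import MotionSummary, RegionStats

    laa_exp = spec.laa_exp_mean + spec.laa_exp_sd * rng.standard_normal()
    laa_insp = spec.laa_insp_mean + spec.laa_insp_sd * rng.standard_normal()

    def draw_metric(name, coupled):
        mean = spec.metric_means[name]
        sd = spec.metric_sds[name]
        slope = spec.laa_slopes.get(name, 0.0) if coupled else 0.0
        resid = np.sqrt(max(sd**2 - (slope * spec.laa_exp_sd) ** 2, 1e-12))
        return mean + slope * (laa_exp - spec.laa_exp_mean) + resid * rng.standard_normal()

    regions = {}
    metric_names = ("s3d", "s2d", "transverse", "apicobasal", "dorsoventral",
                    "angle_mean", "angle_sd")
    for region in ("whole", "Q1", "Q2", "Q3", "Q4"):
        vals = {m: draw_metric(m, coupled=(region == "whole")) for m in metric_names}
        regions[region] = RegionStats(
            n=1600 if region == "whole" else 400,
            mean_s3d=vals["s3d"], mean_s2d=vals["s2d"],
            transverse=vals["transverse"], apicobasal=vals["apicobasal"],
            dorsoventral=vals["dorsoventral"],
            angle_mean=vals["angle_mean"], angle_sd=abs(vals["angle_sd"]),
        )

    ratio = spec.volume_ratio_mean + spec.volume_ratio_sd * rng.standard_normal()
    air_in = max(spec.insp_air_mean_l + spec.insp_air_sd_l * rng.standard_normal(), 1.0)
    air_ex = ratio * air_in

    def draw_edi():
        if rng.random() < spec.edi_upper_fraction:
            return float(rng.uniform(2.0, 6.0))
        return float(rng.uniform(0.3, 1.9))

    edi_l, edi_r = draw_edi(), draw_edi()
    tissue = 0.85
    densito = DensitometrySummary(
        air_volume_insp_l=air_in, air_volume_exp_l=air_ex,
        tissue_volume_insp_l=tissue, tissue_volume_exp_l=tissue,
        lung_volume_insp_l=air_in + tissue, lung_volume_exp_l=air_ex + tissue,
        laa_insp=laa_insp, laa_exp=laa_exp,
        edi_left=edi_l, edi_right=edi_r,
        edi_type_left=classify_edi(edi_l), edi_type_right=classify_edi(edi_r),
        volume_ratio=ratio, qc_pass=bool(ratio < 0.9),
    )
    pft = None
    if spec.pft_means:
        sds = spec.pft_sds or {}
        pft = {
            k: float(mu + sds.get(k, 0.0) * rng.standard_normal())
            for k, mu in spec.pft_means.items()
        }
    return SubjectRecord(
        subject_id=subject_id, group=spec.name,
        motion=MotionSummary(regions=regions),
        densitometry=densito, pft=pft, qc_pass=densito.qc_pass,
    )


def _full_subject(spec, rng, subject_id, phantom_template, reg_config, band_config):
    from . import densitometry as dens
    from . import motionography as motion
    from . import registration as reg
    from .cohort import SubjectRecord

    scale = spec.metric_means["apicobasal"] / _GROUP_METRIC_MEANS["normal"]["apicobasal"]
    jitter = 1.0 + 0.15 * rng.standard_normal()
    amp = (
        0.5 * scale,
        -2.0 * scale * max(jitter, 0.2),
        -10.0 * scale * max(jitter, 0.2),
    )
    p_spec = (phantom_template or PhantomSpec()).with_(
        motion_amplitudes=amp, seed=int(rng.integers(0, 2**31 - 1))
    )
    pair = build_phantom(p_spec)
    field = reg.register(pair.expiration, pair.inspiration, pair.expiration_seg,
                         reg_config)
    summary = dens.summarize(pair.inspiration, pair.expiration,
                             pair.inspiration_seg, pair.expiration_seg)
    ctx = motion.NormalizationContext(
        v_in=summary.lung_volume_insp_l, v_ex=summary.lung_volume_exp_l
    )
    _, msum = motion.analyze(field, pair.expiration_seg, ctx,
                             band_config or motion.BasalBandConfig())
    return SubjectRecord(
        subject_id=subject_id, group=spec.name, motion=msum,
        densitometry=summary, pft=None, qc_pass=summary.qc_pass,
    )


def synth_cohort(
    group_specs=None,
    n_per_group: int | None = None,
    seed: int = 0,
    mode: str = "fast",
    phantom_template: "PhantomSpec | None" = None,
    registration_config=None,
    band_config=None,
):
    """Generate a group-structured cohort of subject records.

    ``mode='fast'`` draws per-subject motion/densitometry summaries directly
    from the group distributions (seconds; intended for statistics testing).
    ``mode='full'`` builds a phantom per subject, registers it and runs the
    whole measurement pipeline (minutes; end-to-end validation).
    Deterministic for fixed specs and seed.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    if isinstance(group_specs, dict):
        group_specs = list(group_specs.values())
    if mode not in ("fast", "full"):
        raise ValueError("mode must be 'fast' or 'full'")
    records = []
    streams = np.random.SeedSequence(seed).spawn(len(group_specs))
    for spec, stream in zip(group_specs, streams):
        rng = np.random.default_rng(stream)
        n = spec.n if n_per_group is None else n_per_group
        for i in range(n):
            sid = f"{spec.name}-{i:03d}"
            if mode == "fast":
                records.append(_fast_subject(spec, rng, sid))
            else:
                records.append(
                    _full_subject(spec, rng, sid, phantom_template,
                                  registration_config, band_config)
                )
    return records
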