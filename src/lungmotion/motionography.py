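"""Diaphragm motion metrics from a deformation field and lung masks.

The diaphragm is not segmented explicitly; its motion is read off the basal
lung — voxels within a configurable band (default 5 mm) above the lowest lung
surface — sampled on a regular pitch grid.  Each sample carries the local
expiration→inspiration displacement split into transverse (x), dorsal–ventral
(y) and apico-basal (z) components, a volume-normalized magnitude, the
xy-plane displacement angle θ, and a quadrant assignment relative to the
lung's basal centre point.

Normalization divides displacement (in cm) by the cubic root of the global
lung volume change (in litres):  s* = s / (V_IN − V_EX)^(1/3), cancelling
inter-subject differences in breathing depth.

Angle convention (xy-plane, apico-basal changes ignored): 0° is the
ventral→dorsal direction, 90° medial, 180° ventral, 270° lateral — the angle
grows from the inside (medial) out (lateral), mirrored consistently between
the two lungs so that left/right reflections leave θ unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError
from .fields import AnalyticDeformation
from .volume import LungSegmentation, world_axes, world_to_index

REGIONS = ("whole", "Q1", "Q2", "Q3", "Q4")
QUADRANT_NAMES = {
    "Q1": "antero-lateral",
    "Q2": "antero-medial",
    "Q3": "postero-medial",
    "Q4": "postero-lateral",
}
MM_PER_CM = 10.0


@dataclass(frozen=True)
class BasalBandConfig:
    band_thickness: float = 5.0   # mm above the basal surface
    sample_pitch: float = 5.0     # mm between samples
    anchor_volume: str = "expiration"

    def __post_init__(self):
        if self.band_thickness < 0:
            raise ValueError("band_thickness must be >= 0")
        if self.sample_pitch <= 0:
            raise ValueError("sample_pitch must be positive")
        if self.anchor_volume not in ("expiration", "inspiration"):
            raise ValueError("anchor_volume must be 'expiration' or 'inspiration'")


@dataclass(frozen=True)
class NormalizationContext:
    """Global lung volumes (litres) defining the normalization divisor."""

    v_in: float
    v_ex: float

    def __post_init__(self):
        if not (self.v_in > self.v_ex):
            raise ValueError(
                "normalization requires V_IN > V_EX (inspiration must inflate)"
            )

    @property
    def divisor(self) -> float:
        return float((self.v_in - self.v_ex) ** (1.0 / 3.0))


@dataclass
class RegionStats:
    """Aggregates for one region (whole diaphragm or a quadrant)."""

    n: int
    mean_s3d: float = float("nan")
    mean_s2d: float = float("nan")
    transverse: float = float("nan")
    apicobasal: float = float("nan")
    dorsoventral: float = float("nan")
    angle_mean: float = float("nan")
    angle_sd: float = float("nan")


@dataclass
class MotionSummary:
    """Per-region motion metrics in the Table-shaped layout (whole + Q1–Q4)."""

    regions: dict = dc_field(default_factory=dict)

    def metric(self, region: str, name: str) -> float:
        return getattr(self.regions[region], name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in REGIONS:
            if region not in self.regions:
                continue
            st = self.regions[region]
            rows.append(
                {
                    "region": region,
                    "n": st.n,
                    "s3d": st.mean_s3d,
                    "s2d": st.mean_s2d,
                    "transverse": st.transverse,
                    "apicobasal": st.apicobasal,
                    "dorsoventral": st.dorsoventral,
                    "angle_mean": st.angle_mean,
                    "angle_sd": st.angle_sd,
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Basal band extraction

def diaphragm_height_map(seg: LungSegmentation, side: str) -> np.ndarray:
    """Per-(x, y) column height (mm) of the lowest lung voxel; NaN off-lung."""
    mask = seg.lung_mask(side)
    if not mask.any():
        raise EmptyMaskError(f"no lung voxels for side {side!r}")
    nz = seg.shape[2]
    zs = world_axes(seg.shape, seg.spacing, seg.origin)[2]
    first = np.argmax(mask, axis=2)                 # lowest z index with lung
    has_lung = mask.any(axis=2)
    hm = np.where(has_lung, zs[first], np.nan)
    return hm


def extract_basal_band(
    seg: LungSegmentation,
    height_map: np.ndarray,
    side: str,
    config: BasalBandConfig = BasalBandConfig(),
) -> np.ndarray:
    """Sample positions (N, 3) mm in the basal band, on the pitch grid.

    A lung voxel at column (x, y) belongs to the band when its z coordinate is
    within ``band_thickness`` of the column's basal surface height.  The band
    is then subsampled by taking every k-th voxel per axis, with
    k = max(1, round(pitch / spacing)).
    """
    mask = seg.lung_mask(side)
    zs = world_axes(seg.shape, seg.spacing, seg.origin)[2]
    band = mask & (zs[None, None, :] <= (height_map[:, :, None] + config.band_thickness))
    steps = tuple(
        max(1, int(round(config.sample_pitch / s))) for s in seg.spacing
    )
    sub = np.zeros_like(band)
    sub[:: steps[0], :: steps[1], :: steps[2]] = True
    band &= sub
    if not band.any():
        raise EmptyMaskError("basal band is empty; check geometry/config")
    idx = np.argwhere(band).astype(float)
    return np.asarray(seg.origin) + idx * np.asarray(seg.spacing)


# --------------------------------------------------------------------------- #
# Sampling and per-sample quantities

def sample_displacements(field, positions: np.ndarray) -> np.ndarray:
    """Displacement (N, 3) mm at sample positions.

    ``field`` may be a closed-form :class:`AnalyticDeformation` (evaluated
    exactly) or a dense deformation field with trilinear interpolation.
    """
    positions = np.asarray(positions, dtype=float)
    if isinstance(field, AnalyticDeformation):
        return field.displacement(positions)
    # dense field object (registration.DeformationField)
    idx = world_to_index(positions, field.spacing, field.origin)
    lo = idx.min()
    hi = (idx - (np.asarray(field.u.shape[:3]) - 1)).max()
    if lo < -1e-6 or hi > 1e-6:
        raise ValueError("sample positions outside the field domain")
    out = np.empty_like(positions)
    for d in range(3):
        out[:, d] = ndimage.map_coordinates(
            field.u[..., d], idx.T, order=1, mode="nearest"
        )
    return out


def displacement_angle(u_x, u_y, lung_side) -> np.ndarray:
    """xy-plane displacement angle θ in degrees, [0, 360).

    θ = atan2(medial, dorsal) where dorsal is the +y component and medial the
    component toward the midline (−x on the left lung, +x on the right, with
    +x = patient-left).  Samples with a zero xy-projection get NaN (angle
    undefined; excluded from angle statistics).
    """
    u_x = np.asarray(u_x, dtype=float)
    u_y = np.asarray(u_y, dtype=float)
    side = np.asarray(lung_side)
    medial_sign = np.where(side == "left", -1.0, 1.0)
    m = medial_sign * u_x
    theta = np.degrees(np.arctan2(m, u_y)) % 360.0
    zero = (u_x == 0.0) & (u_y == 0.0)
    return np.where(zero, np.nan, theta)


def lung_center(positions: np.ndarray) -> tuple[float, float]:
    """Basal centre point: midpoints of the x and y coordinate ranges."""
    x = positions[:, 0]
    y = positions[:, 1]
    return (
        0.5 * (float(x.min()) + float(x.max())),
        0.5 * (float(y.min()) + float(y.max())),
    )


def assign_quadrant(positions: np.ndarray, lung_side: str, center) -> np.ndarray:
    """Quadrant codes 1–4 for basal samples of one lung.

    Anterior means y < c_y (ventral of the centre), posterior y >= c_y.
    Lateral means farther from the midline than c_x (ties count as medial).
    Q1 antero-lateral, Q2 antero-medial, Q3 postero-medial, Q4 postero-lateral.
    """
    cx, cy = center
    x = positions[:, 0]
    y = positions[:, 1]
    anterior = y < cy
    if lung_side == "left":      # +x side: larger x is farther from midline
        lateral = x > cx
    elif lung_side == "right":
        lateral = x < cx
    else:
        raise ValueError("lung_side must be 'left' or 'right'")
    quad = np.where(
        anterior,
        np.where(lateral, 1, 2),
        np.where(lateral, 4, 3),
    )
    return quad.astype(int)


# --------------------------------------------------------------------------- #
# Assembly

def build_samples(
    field,
    seg: LungSegmentation,
    ctx: NormalizationContext,
    config: BasalBandConfig = BasalBandConfig(),
) -> pd.DataFrame:
    """Per-sample displacement table for both lungs.

    Columns: position (x, y, z mm), raw components (ux, uy, uz mm), side,
    quadrant, s3d_mm, normalized metrics (dimensionless; displacement in cm
    over (ΔV litres)^(1/3)) and θ (degrees, NaN when undefined).
    """
    frames = []
    for side in ("left", "right"):
        if not seg.lung_mask(side).any():
            continue
        hm = diaphragm_height_map(seg, side)
        pos = extract_basal_band(seg, hm, side, config)
        u = sample_displacements(field, pos)
        frames.append(_samples_frame(pos, u, side, ctx))
    if not frames:
        raise EmptyMaskError("no lung voxels on either side")
    return pd.concat(frames, ignore_index=True)


def _samples_frame(pos, u, side, ctx: NormalizationContext) -> pd.DataFrame:
    quad = assign_quadrant(pos, side, lung_center(pos))
    df = pd.DataFrame(
        {
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "ux": u[:, 0],
            "uy": u[:, 1],
            "uz": u[:, 2],
            "side": side,
            "quadrant": quad,
        }
    )
    df["s3d_mm"] = np.linalg.norm(u, axis=1)
    df["theta"] = displacement_angle(u[:, 0], u[:, 1], np.full(len(df), side))
    return normalize(df, ctx)


def normalize(samples: pd.DataFrame, ctx: NormalizationContext) -> pd.DataFrame:
    """Attach normalized metrics: (component in cm) / (ΔV in L)^(1/3)."""
    div = ctx.divisor
    out = samples.copy()
    for comp, col in (("ux", "ux_norm"), ("uy", "uy_norm"), ("uz", "uz_norm")):
        out[col] = out[comp] / MM_PER_CM / div
    out["s3d_norm"] = out["s3d_mm"] / MM_PER_CM / div
    out["s2d_norm"] = np.hypot(out["ux"], out["uy"]) / MM_PER_CM / div
    return out


def summarize(samples: pd.DataFrame) -> MotionSummary:
    """Region aggregates: whole diaphragm (both lungs pooled) and Q1–Q4
    (left + right pooled after per-lung quadrant assignment).

    Magnitude metrics are means of per-sample normalized norms; per-axis
    metrics are |mean of signed normalized components| so that opposing
    motion cancels (this is why whole-diaphragm transverse motion is near
    zero on symmetric subjects).  θ statistics are arithmetic mean/SD on
    [0, 360) over angle-defined samples only.
    """
    if len(samples) == 0:
        raise EmptyMaskError("no samples to summarize")
    summary = MotionSummary()
    groups = {"whole": samples}
    for q in (1, 2, 3, 4):
        groups[f"Q{q}"] = samples[samples["quadrant"] == q]
    for region, df in groups.items():
        n = len(df)
        if n == 0:
            summary.regions[region] = RegionStats(n=0)
            continue
        theta = df["theta"].dropna()
        summary.regions[region] = RegionStats(
            n=n,
            mean_s3d=float(df["s3d_norm"].mean()),
            mean_s2d=float(df["s2d_norm"].mean()),
            transverse=abs(float(df["ux_norm"].mean())),
            apicobasal=abs(float(df["uz_norm"].mean())),
            dorsoventral=abs(float(df["uy_norm"].mean())),
            angle_mean=float(theta.mean()) if len(theta) else float("nan"),
            angle_sd=float(theta.std(ddof=1)) if len(theta) > 1 else (
                0.0 if len(theta) == 1 else float("nan")
            ),
        )
    return summary


def analyze(field, seg, ctx, config: BasalBandConfig = BasalBandConfig()):
    """Convenience: samples plus their summary in one call."""
    samples = build_samples(field, seg, ctx, config)
    return samples, summarize(samples)
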