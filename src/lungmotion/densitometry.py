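"""Voxel densitometry, low-attenuation indices and subject-level QC.

The lung is modelled as a linear mixture of air (``hu_air``) and tissue
(``hu_tissue``): a voxel at HU value *I* has tissue fraction

    beta(I) = clip((I - hu_air) / (hu_tissue - hu_air), 0, 1)

and air fraction ``1 - beta``.  Air/tissue volumes are voxel-volume weighted
sums of these fractions over the lung mask, reported in litres.

Emphysema burden is quantified with the classic low-attenuation-area indices:
%LAA_insp (share of lung voxels strictly below -950 HU on the inspiration
scan) and %LAA_exp (strictly below -856 HU on expiration, an air-trapping
index).  The emphysema distribution index (EDI) is the upper-to-lower-lobe
ratio of %LAA_insp per lung; EDI >= 2 is upper-lobe-predominant, below 2 is
diffuse.  Scan-pair quality control rejects subjects whose expiratory/
inspiratory air-volume ratio is not strictly below 0.9 (under-inspiration or
under-expiration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import DegenerateDenominatorError, EmptyMaskError
from .volume import ImageVolume, LungSegmentation

MM3_PER_L = 1.0e6

EDI_UPPER = "upper-lobe-predominant"
EDI_DIFFUSE = "diffuse"
EDI_UNDEFINED = "undefined"


@dataclass(frozen=True)
class DensityConfig:
    """Thresholds and mixing constants for lung densitometry."""

    hu_air: float = -1000.0
    hu_tissue: float = 55.0
    laa_insp_threshold: float = -950.0
    laa_exp_threshold: float = -856.0
    volume_ratio_cutoff: float = 0.9
    edi_cutoff: float = 2.0

    def __post_init__(self):
        if not (
            self.hu_air < self.laa_insp_threshold < self.laa_exp_threshold < self.hu_tissue
        ):
            raise ValueError(
                "expected hu_air < laa_insp_threshold < laa_exp_threshold < hu_tissue"
            )
        if not (0.0 < self.volume_ratio_cutoff <= 1.0):
            raise ValueError("volume_ratio_cutoff must be in (0, 1]")
        if self.edi_cutoff <= 0:
            raise ValueError("edi_cutoff must be positive")


DEFAULT_DENSITY = DensityConfig()


def tissue_fraction(hu, config: DensityConfig = DEFAULT_DENSITY):
    """Tissue fraction in [0, 1] from HU under the linear air/tissue mixture."""
    hu = np.asarray(hu, dtype=float)
    beta = (hu - config.hu_air) / (config.hu_tissue - config.hu_air)
    out = np.clip(beta, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def air_fraction(hu, config: DensityConfig = DEFAULT_DENSITY):
    return 1.0 - tissue_fraction(hu, config)


def _as_mask(volume: ImageVolume, mask) -> np.ndarray:
    if isinstance(mask, LungSegmentation):
        mask = mask.lung_mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask not aligned with volume")
    if not mask.any():
        raise EmptyMaskError("empty lung mask")
    return mask


def air_volume(volume: ImageVolume, mask, config: DensityConfig = DEFAULT_DENSITY) -> float:
    """Air volume in litres over the masked region."""
    m = _as_mask(volume, mask)
    frac = air_fraction(volume.values[m], config)
    return float(frac.sum() * volume.voxel_volume_mm3 / MM3_PER_L)


def tissue_volume(volume: ImageVolume, mask, config: DensityConfig = DEFAULT_DENSITY) -> float:
    """Tissue volume in litres over the masked region."""
    m = _as_mask(volume, mask)
    frac = tissue_fraction(volume.values[m], config)
    return float(frac.sum() * volume.voxel_volume_mm3 / MM3_PER_L)


def lung_volume(volume_or_seg, mask=None) -> float:
    """Total (air + tissue) volume in litres of the masked region."""
    if isinstance(volume_or_seg, LungSegmentation) and mask is None:
        seg = volume_or_seg
        return float(seg.require_lung().sum() * seg.voxel_volume_mm3 / MM3_PER_L)
    vol = volume_or_seg
    m = _as_mask(vol, mask)
    return float(m.sum() * vol.voxel_volume_mm3 / MM3_PER_L)


def percent_laa(volume: ImageVolume, mask, threshold: float) -> float:
    """Percentage of masked voxels with HU strictly below ``threshold``."""
    m = _as_mask(volume, mask)
    vals = volume.values[m]
    return float(100.0 * np.count_nonzero(vals < threshold) / vals.size)


def percent_laa_by_lobe(
    volume: ImageVolume, seg: LungSegmentation, threshold: float
) -> dict[str, float]:
    """Per-lobe %LAA plus the pooled RUL∪RML region used by the right-lung EDI."""
    out = {}
    for name in ("LUL", "LLL", "RUL", "RML", "RLL"):
        out[name] = percent_laa(volume, seg.lobe_mask(name), threshold)
    out["RUL+RML"] = percent_laa(volume, seg.region_mask(("RUL", "RML")), threshold)
    return out


def compute_edi(laa_by_lobe: dict[str, float]) -> tuple[float, float]:
    """Emphysema distribution index per lung from per-lobe %LAA_insp.

    EDI(left) = %LAA(LUL) / %LAA(LLL); EDI(right) = %LAA(RUL∪RML) / %LAA(RLL),
    where the right numerator is %LAA computed on the pooled upper+middle voxel
    set, not a sum of two percentages.

    Raises
    ------
    DegenerateDenominatorError
        If a lower-lobe %LAA is zero (EDI undefined for that lung).
    """
    try:
        upper_right = laa_by_lobe["RUL+RML"]
    except KeyError:
        raise KeyError("laa_by_lobe must contain the pooled 'RUL+RML' region")
    if laa_by_lobe["LLL"] == 0.0 or laa_by_lobe["RLL"] == 0.0:
        raise DegenerateDenominatorError("lower-lobe %LAA is zero; EDI undefined")
    edi_left = laa_by_lobe["LUL"] / laa_by_lobe["LLL"]
    edi_right = upper_right / laa_by_lobe["RLL"]
    return float(edi_left), float(edi_right)


def classify_edi(edi_value, config: DensityConfig = DEFAULT_DENSITY) -> str:
    """Type an EDI value: >= cutoff upper-lobe-predominant, below diffuse.

    ``None`` (or NaN) propagates as ``"undefined"``.
    """
    if edi_value is None or (isinstance(edi_value, float) and np.isnan(edi_value)):
        return EDI_UNDEFINED
    return EDI_UPPER if edi_value >= config.edi_cutoff else EDI_DIFFUSE


def qc_volume_ratio(
    insp_air_l: float, exp_air_l: float, config: DensityConfig = DEFAULT_DENSITY
) -> tuple[float, bool]:
    """Expiratory/inspiratory air-volume ratio and its strict-< QC verdict."""
    if insp_air_l <= 0:
        raise ValueError("inspiration air volume must be positive")
    ratio = exp_air_l / insp_air_l
    return float(ratio), bool(ratio < config.volume_ratio_cutoff)


@dataclass
class DensitometrySummary:
    """Subject-level densitometry: volumes, %LAA indices, EDI typing and QC."""

    air_volume_insp_l: float
    air_volume_exp_l: float
    tissue_volume_insp_l: float
    tissue_volume_exp_l: float
    lung_volume_insp_l: float
    lung_volume_exp_l: float
    laa_insp: float
    laa_exp: float
    laa_insp_by_lobe: dict = field(default_factory=dict)
    air_volume_by_lobe_insp_l: dict = field(default_factory=dict)
    tissue_volume_by_lobe_insp_l: dict = field(default_factory=dict)
    edi_left: float | None = None
    edi_right: float | None = None
    edi_type_left: str = EDI_UNDEFINED
    edi_type_right: str = EDI_UNDEFINED
    volume_ratio: float = float("nan")
    qc_pass: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    insp: ImageVolume,
    exp: ImageVolume,
    insp_seg: LungSegmentation,
    exp_seg: LungSegmentation,
    config: DensityConfig = DEFAULT_DENSITY,
) -> DensitometrySummary:
    """Full densitometry pass over an inspiration/expiration scan pair."""
    insp_mask = insp_seg.require_lung()
    exp_mask = exp_seg.require_lung()

    air_in = air_volume(insp, insp_mask, config)
    air_ex = air_volume(exp, exp_mask, config)
    ratio, qc = qc_volume_ratio(air_in, air_ex, config)

    laa_lobes = percent_laa_by_lobe(insp, insp_seg, config.laa_insp_threshold)
    try:
        edi_l, edi_r = compute_edi(laa_lobes)
    except DegenerateDenominatorError:
        edi_l = edi_r = None

    air_lobes = {}
    tis_lobes = {}
    for name in ("LUL", "LLL", "RUL", "RML", "RLL"):
        lm = insp_seg.lobe_mask(name)
        if lm.any():
            air_lobes[name] = air_volume(insp, lm, config)
            tis_lobes[name] = tissue_volume(insp, lm, config)

    return DensitometrySummary(
        air_volume_insp_l=air_in,
        air_volume_exp_l=air_ex,
        tissue_volume_insp_l=tissue_volume(insp, insp_mask, config),
        tissue_volume_exp_l=tissue_volume(exp, exp_mask, config),
        lung_volume_insp_l=lung_volume(insp, insp_mask),
        lung_volume_exp_l=lung_volume(exp, exp_mask),
        laa_insp=percent_laa(insp, insp_mask, config.laa_insp_threshold),
        laa_exp=percent_laa(exp, exp_mask, config.laa_exp_threshold),
        laa_insp_by_lobe=laa_lobes,
        air_volume_by_lobe_insp_l=air_lobes,
        tissue_volume_by_lobe_insp_l=tis_lobes,
        edi_left=edi_l,
        edi_right=edi_r,
        edi_type_left=classify_edi(edi_l, config),
        edi_type_right=classify_edi(edi_r, config),
        volume_ratio=ratio,
        qc_pass=qc,
    )
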