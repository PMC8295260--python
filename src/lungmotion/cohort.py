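"""Cohort assembly and group statistics for diaphragm-motion studies.

Mirrors the analysis plan of a three-group (normal / emphysema / IPF) motion
study: pairwise independent t-tests (Welch by default), one-way ANOVA with
Holm-adjusted post-hoc contrasts computed only when the ANOVA is significant,
and Pearson correlations of motion metrics against severity indices (%LAA)
and pulmonary-function variables.  Subjects failing the expiratory/
inspiratory air-volume-ratio QC — and, when spirometry is present, emphysema
subjects without airflow obstruction (FEV1/FVC >= 70%) — are excluded before
any statistic is computed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import DensitometrySummary
from .motionography import REGIONS, MotionSummary

GROUPS = ("normal", "emphysema", "IPF")
#: Metrics reported per region (the displacement rows of the group tables).
METRICS = (
    "s3d",
    "s2d",
    "transverse",
    "apicobasal",
    "dorsoventral",
    "angle_mean",
    "angle_sd",
)
PFT_FIELDS = ("fev1_pp", "fvc_pp", "fev1_fvc", "post_fvc_pp")


@dataclass
class SubjectRecord:
    """One (synthetic) subject: group label, motion and densitometry summaries."""

    subject_id: str
    group: str
    motion: MotionSummary
    densitometry: DensitometrySummary | None = None
    pft: dict | None = None
    qc_pass: bool = True

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")

    def flatten(self) -> dict:
        row = {"subject_id": self.subject_id, "group": self.group, "qc_pass": self.qc_pass}
        for region in REGIONS:
            if region not in self.motion.regions:
                continue
            st = self.motion.regions[region]
            row[f"s3d_{region}"] = st.mean_s3d
            row[f"s2d_{region}"] = st.mean_s2d
            row[f"transverse_{region}"] = st.transverse
            row[f"apicobasal_{region}"] = st.apicobasal
            row[f"dorsoventral_{region}"] = st.dorsoventral
            row[f"angle_mean_{region}"] = st.angle_mean
            row[f"angle_sd_{region}"] = st.angle_sd
        d = self.densitometry
        if d is not None:
            row.update(
                laa_insp=d.laa_insp,
                laa_exp=d.laa_exp,
                volume_ratio=d.volume_ratio,
                edi_left=d.edi_left,
                edi_right=d.edi_right,
                edi_type_left=d.edi_type_left,
                edi_type_right=d.edi_type_right,
            )
        if self.pft:
            row.update(self.pft)
        return row


def cohort_frame(records) -> pd.DataFrame:
    """Flatten subject records into one row per subject."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.flatten() for r in records])


def apply_qc(df: pd.DataFrame) -> pd.DataFrame:
    """Drop QC failures and, when spirometry is present, emphysema subjects
    without post-bronchodilator obstruction (FEV1/FVC >= 70%)."""
    out = df
    if "qc_pass" in out.columns:
        out = out[out["qc_pass"].astype(bool)]
    if "fev1_fvc" in out.columns:
        gate = (out["group"] != "emphysema") | (out["fev1_fvc"] < 70.0)
        out = out[gate | out["fev1_fvc"].isna()]
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------- #
# Statistics

def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order.

    Sort ascending, multiply the k-th smallest by (m − k), enforce a running
    maximum, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class GroupComparison:
    metric: str
    groups: tuple
    means: dict
    t_stats: dict
    p_values: dict
    anova_f: float
    anova_p: float
    holm: dict | None
    significant: dict
    alpha: float = 0.05
    welch: bool = True


def compare_groups(
    cohort, metric: str, alpha: float = 0.05, welch: bool = True, qc: bool = True
) -> GroupComparison:
    """Pairwise t-tests + one-way ANOVA for one metric across the groups.

    Holm-adjusted pairwise p-values are reported only when the ANOVA p-value
    is below ``alpha`` (the study's post-hoc gating).  ``welch`` selects the
    unequal-variance t-test; pass False for Student's pooled variant.
    """
    df = cohort_frame(cohort)
    if qc:
        df = apply_qc(df)
    present = [g for g in GROUPS if (df["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("compare_groups needs at least two groups")
    samples = {}
    for g in present:
        x = df.loc[df["group"] == g, metric].dropna().to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than two subjects")
        if np.ptp(x) == 0.0:
            raise ValueError(f"metric {metric!r} is constant within group {g!r}")
        samples[g] = x

    means = {g: float(x.mean()) for g, x in samples.items()}
    t_stats, p_values = {}, {}
    for a, b in itertools.combinations(present, 2):
        t, p = stats.ttest_ind(samples[a], samples[b], equal_var=not welch)
        t_stats[(a, b)] = float(t)
        p_values[(a, b)] = float(p)

    if len(present) >= 3:
        f, anova_p = stats.f_oneway(*(samples[g] for g in present))
    else:
        f, anova_p = stats.f_oneway(*(samples[g] for g in present))
    anova_f, anova_p = float(f), float(anova_p)

    holm = None
    if anova_p < alpha and len(p_values) > 1:
        pairs = list(p_values)
        adj = holm_adjust([p_values[k] for k in pairs])
        holm = dict(zip(pairs, adj.tolist()))

    significant = {k: p < alpha for k, p in p_values.items()}
    return GroupComparison(
        metric=metric,
        groups=tuple(present),
        means=means,
        t_stats=t_stats,
        p_values=p_values,
        anova_f=anova_f,
        anova_p=anova_p,
        holm=holm,
        significant=significant,
        alpha=alpha,
        welch=welch,
    )


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int


def pearson(cohort, x_field: str, y_field: str, qc: bool = True) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    df = cohort_frame(cohort)
    if qc:
        df = apply_qc(df)
    sub = df[[x_field, y_field]].dropna()
    x = sub[x_field].to_numpy(dtype=float)
    y = sub[y_field].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("pearson needs at least three complete observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("pearson is undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x=x_field, y=y_field, r=float(r), p=float(p), n=int(x.size))


# --------------------------------------------------------------------------- #
# Report tables

def _comparison_table(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    present = [g for g in GROUPS if (df["group"] == g).any()]
    rows = []
    for region in REGIONS:
        for metric in METRICS:
            col = f"{metric}_{region}"
            if col not in df.columns:
                continue
            row = {"region": region, "metric": metric}
            for g in present:
                row[f"mean_{g}"] = float(df.loc[df["group"] == g, col].mean())
            if len(present) >= 2:
                cmp = compare_groups(df, col, alpha=alpha, qc=False)
                row["anova_f"] = cmp.anova_f
                row["anova_p"] = cmp.anova_p
                for (a, b), p in cmp.p_values.items():
                    row[f"t_p_{a}_vs_{b}"] = p
                for a, b in itertools.combinations(present, 2):
                    row[f"holm_p_{a}_vs_{b}"] = (
                        cmp.holm[(a, b)] if cmp.holm is not None else np.nan
                    )
                row["anova_significant"] = cmp.anova_p < alpha
            rows.append(row)
    return pd.DataFrame(rows)


def _edi_table(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Upper-lobe-predominant vs diffuse comparison, emphysema lungs only."""
    emph = df[df["group"] == "emphysema"]
    if emph.empty or "edi_type_left" not in emph.columns:
        return pd.DataFrame()
    lungs = []
    for side in ("left", "right"):
        sub = emph[["subject_id"] + [f"{m}_whole" for m in METRICS]].copy()
        sub["edi_type"] = emph[f"edi_type_{side}"].to_numpy()
        lungs.append(sub)
    lungs = pd.concat(lungs, ignore_index=True)
    lungs = lungs[lungs["edi_type"].isin(["upper-lobe-predominant", "diffuse"])]
    rows = []
    for metric in METRICS:
        col = f"{metric}_whole"
        up = lungs.loc[lungs["edi_type"] == "upper-lobe-predominant", col].dropna()
        di = lungs.loc[lungs["edi_type"] == "diffuse", col].dropna()
        row = {
            "metric": metric,
            "n_upper": int(len(up)),
            "n_diffuse": int(len(di)),
            "mean_upper": float(up.mean()) if len(up) else np.nan,
            "mean_diffuse": float(di.mean()) if len(di) else np.nan,
        }
        if len(up) >= 2 and len(di) >= 2 and up.std() + di.std() > 0:
            t, p = stats.ttest_ind(up, di, equal_var=False)
            row["t"] = float(t)
            row["p"] = float(p)
            row["significant"] = p < alpha
        rows.append(row)
    return pd.DataFrame(rows)


def _correlation_table(df: pd.DataFrame, group: str, x_fields, alpha: float) -> pd.DataFrame:
    sub = df[df["group"] == group]
    rows = []
    for metric in METRICS:
        col = f"{metric}_whole"
        if col not in sub.columns:
            continue
        row = {"metric": metric}
        for xf in x_fields:
            if xf not in sub.columns or sub[xf].dropna().nunique() < 2:
                continue
            try:
                res = pearson(sub, xf, col, qc=False)
            except ValueError:
                continue
            row[f"r_{xf}"] = res.r
            row[f"p_{xf}"] = res.p
            row[f"n_{xf}"] = res.n
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(records, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Report tables: per-region group comparison, EDI-type comparison
    (emphysema only), and %LAA / PFT correlation tables.

    Regeneration is deterministic given the cohort table.
    """
    df = apply_qc(cohort_frame(records))
    if df.empty:
        raise ValueError("cohort is empty after QC")
    report = {"group_comparison": _comparison_table(df, alpha)}
    edi = _edi_table(df, alpha)
    if not edi.empty:
        report["edi_comparison"] = edi
    if "laa_insp" in df.columns and (df["group"] == "emphysema").any():
        report["correlation_laa"] = _correlation_table(
            df, "emphysema", ("laa_insp", "laa_exp"), alpha
        )
    pft_present = [f for f in PFT_FIELDS if f in df.columns]
    if pft_present:
        for g in ("emphysema", "IPF"):
            if (df["group"] == g).any():
                report[f"correlation_pft_{g}"] = _correlation_table(
                    df, g, pft_present, alpha
                )
    return report


def write_report(report: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, table in report.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
        summary[name] = {"rows": int(len(table)), "columns": list(table.columns)}
    (outdir / "report_summary.json").write_text(json.dumps(summary, indent=2))
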