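"""Group statistics on a synthetic three-group cohort.

Draws normal / emphysema / IPF subjects from the configured group
distributions (fast mode: motion summaries sampled directly), then runs the
study's analysis plan: per-metric ANOVA with Holm-adjusted pairwise
contrasts, and Pearson correlations of motion metrics against %LAA in the
emphysema group.
"""

from lungmotion.cohort import build_report, cohort_frame, compare_groups, pearson
from lungmotion.phantom import synth_cohort

records = synth_cohort(seed=7)          # 29 normal / 50 emphysema / 51 IPF
df = cohort_frame(records)

cmp = compare_groups(df, "apicobasal_whole")
print("whole-diaphragm apico-basal displacement (normalized):")
for g, m in cmp.means.items():
    print(f"  {g:10s} mean {m:.2f}")
print(f"  ANOVA p = {cmp.anova_p:.4f}")
if cmp.holm:
    for pair_, p in cmp.holm.items():
        print(f"  Holm-adjusted {pair_[0]} vs {pair_[1]}: p = {p:.4f}")

corr = pearson(df[df.group == "emphysema"], "laa_exp", "apicobasal_whole",
               qc=False)
print(f"\nemphysema %LAA_exp vs apico-basal: r = {corr.r:.3f} "
      f"(p = {corr.p:.2g}, n = {corr.n})")
print("air trapping (higher %LAA_exp) goes with reduced apico-basal "
      "diaphragm excursion — the generator injects this dependence and the "
      "analysis recovers it.")

report = build_report(records)
print("\nreport tables:", ", ".join(report.keys()))
print(report["group_comparison"].head(7).round(3).to_string(index=False))
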