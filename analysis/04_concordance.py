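"""Three-platform concordance on the simulated data.

Joins expression and protein calls, partitions genes into the eight Venn
groups, tests RNA-protein association, compares group expression
distributions, and stratifies protein detection by expression quantile.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, load_or_simulate
from xconcord import (
    association_test, bin_overlap, build_table, build_hpa_subset,
    contingency_rna_protein, ks_one_sided, overlap_summary, quantify, venn,
)

ds = load_or_simulate()
res = quantify(ds.alignments, ds.genes)
calls = build_hpa_subset(ds.antibodies)
records = build_table(res.expression, calls)

v = venn(records)
venn_df = pd.DataFrame(
    [{"group": g, "count": v[g], "percent": round(100 * v[g] / v.total, 2)}
     for g in ("A", "B", "C", "AB", "AC", "BC", "ABC", "none")]
)
venn_df.to_csv(RESULTS / "sim_venn.tsv", sep="\t", index=False)
print(venn_df.to_string(index=False))

summary = overlap_summary(v)
summary.to_csv(RESULTS / "sim_overlap.tsv", sep="\t", index=False, float_format="%.2f")

rows = []
for platform in ("ihc", "if"):
    r = association_test(contingency_rna_protein(records, platform))
    rows.append({"comparison": f"rna_vs_{platform}", "method": r.method,
                 "statistic": round(r.statistic, 3), "p_value": r.p_value})
all_rpkm = [r.rpkm for r in records]
for group in ("C", "BC"):
    vals = [r.rpkm for r in records if r.venn_group == group]
    if len(vals) >= 2:
        r = ks_one_sided(vals, all_rpkm, "lower")
        rows.append({"comparison": f"{group}_expression_lower_than_all",
                     "method": r.method, "statistic": round(r.statistic, 4),
                     "p_value": r.p_value})
tests = pd.DataFrame(rows)
tests.to_csv(RESULTS / "sim_tests.tsv", sep="\t", index=False)
print()
print(tests.to_string(index=False))

bo = bin_overlap(records, n_bins=25)
bo.to_frame().to_csv(RESULTS / "sim_bins.tsv", sep="\t", index=False, float_format="%.2f")
halves = pd.DataFrame([vars(bo.top_half), vars(bo.bottom_half),
                       vars(bo.top_5pct), vars(bo.bottom_5pct)])
halves.to_csv(RESULTS / "sim_bins_halves.tsv", sep="\t", index=False, float_format="%.2f")
sup = bin_overlap(records, n_bins=25, restrict_supportive_wb=True)
print()
print("detection by expression stratum (all antibodies / supportive-WB only):")
for label, a, b in (("upper 50%", bo.top_half, sup.top_half),
                    ("lower 50%", bo.bottom_half, sup.bottom_half)):
    print(f"  {label}: IHC {a.pct_ihc_present:.1f}% / {b.pct_ihc_present:.1f}%   "
          f"IF {a.pct_if_present:.1f}% / {b.pct_if_present:.1f}%")
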