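"""Full concordance analysis over the deterministic published-counts fixture.

Every number here is recomputed by the pipeline from the 2749-gene fixture
tables; these are the values the README's worked example quotes.
"""

import pandas as pd

from _common import RESULTS
from xconcord import (
    association_test, build_table, contingency_rna_protein, ks_one_sided,
    overlap_summary, published_counts_fixture, venn,
)
from xconcord.group_stats import score_distribution, supportive_ratio

RESULTS.mkdir(parents=True, exist_ok=True)
expr, calls = published_counts_fixture()
records = build_table(expr, calls)

v = venn(records)
venn_df = pd.DataFrame(
    [{"group": g, "count": v[g], "percent": round(100 * v[g] / v.total, 1)}
     for g in ("A", "B", "C", "AB", "AC", "BC", "ABC", "none")]
)
venn_df.to_csv(RESULTS / "fixture_venn.tsv", sep="\t", index=False)
print(venn_df.to_string(index=False))

summary = overlap_summary(v)
summary.to_csv(RESULTS / "fixture_overlap.tsv", sep="\t", index=False,
               float_format="%.4f")
print()
print(summary.to_string(index=False))

rows = []
for platform in ("ihc", "if"):
    t = contingency_rna_protein(records, platform)
    r = association_test(t, correction=True)
    rows.append({"comparison": f"rna_vs_{platform}", "method": r.method,
                 "statistic": round(r.statistic, 3), "p_value": r.p_value})
all_rpkm = [r.rpkm for r in records]
for group in ("C", "BC"):
    vals = [r.rpkm for r in records if r.venn_group == group]
    r = ks_one_sided(vals, all_rpkm, "lower")
    rows.append({"comparison": f"{group}_expression_lower_than_all",
                 "method": r.method, "statistic": round(r.statistic, 4),
                 "p_value": r.p_value})
tests = pd.DataFrame(rows)
tests.to_csv(RESULTS / "fixture_tests.tsv", sep="\t", index=False)
print()
print(tests.to_string(index=False))

d_abc = score_distribution(records, "ABC", "if")
d_b = score_distribution(records, "B", "if")
print(f"\nIF supportive fractions: ABC {d_abc.supportive_fraction:.3f}, "
      f"B {d_b.supportive_fraction:.3f}, "
      f"ratio {supportive_ratio(d_abc, d_b):.2f}")
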