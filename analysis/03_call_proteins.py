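"""Build the non-redundant protein-call subset from the simulated panel.

Keeps genes with both IHC and IF data, selecting the best-scoring IF
antibody per gene, and writes the calls to scratch/.
"""

from _common import RESULTS, SCRATCH, load_or_simulate
from xconcord import build_hpa_subset
from xconcord import io as xio

ds = load_or_simulate()
calls = build_hpa_subset(ds.antibodies)
xio.write_calls_table(calls, SCRATCH / "calls.tsv")

n_ihc = sum(c.ihc_present for c in calls)
n_if = sum(c.if_present for c in calls)
print(f"antibodies in panel: {len(ds.antibodies)}")
print(f"genes in non-redundant subset: {len(calls)}")
print(f"IHC present: {n_ihc} ({100 * n_ihc / len(calls):.1f}%)")
print(f"IF present:  {n_if} ({100 * n_if / len(calls):.1f}%)")
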