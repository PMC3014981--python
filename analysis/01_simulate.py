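"""Generate the study-scale synthetic dataset used by the later scripts.

Draws 2000 genes with zero-inflated log-normal expression, 200k 35-bp reads
with multi-mapping decoys, and a ~2600-antibody panel, then writes the raw
files to scratch/sim/.
"""

from _common import SIM_CONFIG, load_or_simulate

ds = load_or_simulate()
n_multi = int((ds.read_truth.n_decoys > 0).sum())
print(f"genes:      {len(ds.genes)}")
print(f"reads:      {len(ds.alignments)} (read length {SIM_CONFIG.read_length} bp)")
print(f"  multi-mapped: {n_multi} ({100 * n_multi / len(ds.alignments):.1f}%)")
print(f"  expected ambiguous rate: {100 * SIM_CONFIG.expected_ambiguous_rate:.1f}%")
print(f"antibodies: {len(ds.antibodies)}")
print(f"silent genes (pi0 = {SIM_CONFIG.pi_zero}): "
      f"{int((~ds.truth.expressed).sum())} of {SIM_CONFIG.n_genes}")
print("raw data -> scratch/sim/")
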