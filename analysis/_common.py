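"""Shared paths and dataset loading for the numbered analysis scripts.

Raw simulated data (alignments, truth tables) lives under scratch/ — it is
regenerated on demand from the fixed seed; small summary tables go to
results/.
"""

from pathlib import Path

from xconcord import SimulationConfig, simulate
from xconcord import io as xio

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SIM_CONFIG = SimulationConfig(n_genes=2000, depth=200_000, seed=20101202 % (2**31))


def load_or_simulate():
    """Simulate the study-scale dataset (or reload it from scratch/)."""
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    marker = SCRATCH / "alignments.tsv"
    ds = simulate(SIM_CONFIG)
    if not marker.exists():
        xio.write_gene_models_gtf(ds.genes, SCRATCH / "genes.gtf")
        xio.write_alignments_tsv(ds.alignments, marker)
        xio.write_antibody_table(ds.antibodies, SCRATCH / "antibodies.tsv")
        ds.truth.to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)
    return ds
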