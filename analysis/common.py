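"""Shared paths and the study seed for the numbered analysis drivers.

The scenario inputs (notably the 2,000 x 74 rank matrix) are bulky and fully
regenerable, so they live under ``scratch/``; the tables each step derives
are written under ``results/``.
"""

from pathlib import Path

SEED = 1

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "scenario"
RESULTS = ROOT / "results"

SCENARIO_PATHS = {
    "rank_matrix": SCRATCH / "rank_matrix.tsv",
    "metadata": SCRATCH / "instances.tsv",
    "gene_sets": SCRATCH / "gene_sets.gmt",
    "side_effects": SCRATCH / "side_effects.tsv",
    "synonyms": SCRATCH / "synonyms.tsv",
}
GROUNDTRUTH = RESULTS / "groundtruth.tsv"
DP_EDGES = RESULTS / "dp_edges.tsv"
DSE_EDGES = RESULTS / "dse_edges.tsv"
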