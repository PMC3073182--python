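"""Merge the two layers over shared drugs and score process-effect pairs.

Each side effect is scored against every process its drugs perturb
(score = CD/TD); permutation-derived thresholds (1,000 draws per observed TD,
p < 0.05) mark the significant pairs.  The step closes by checking the
significant set against the planted ground truth.
"""

import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DP_EDGES, DSE_EDGES, GROUNDTRUTH, RESULTS, SEED

import numpy as np

from pdsenet import io as pio
from pdsenet.abc import apply_thresholds, co_occurrence, merge_networks, permutation_thresholds


def read_planted_links():
    with open(GROUNDTRUTH) as fh:
        return {(r["source_id"], r["target_id"], r["direction"])
                for r in csv.DictReader(fh, delimiter="\t")
                if r["layer"] == "process_effect"}


def main() -> None:
    network = merge_networks(pio.read_dp_edges(DP_EDGES), pio.read_dse_edges(DSE_EDGES))
    print(f"bridge: {network.summary()}")

    significant = set()
    seeds = np.random.SeedSequence(SEED).spawn(2)
    for (direction, dialect), seed in zip((("up", "additional2"), ("down", "additional3")), seeds):
        assocs = co_occurrence(network, min_drugs=2, direction=direction)
        table = permutation_thresholds(network, n_perm=1000, alpha=0.05, seed=seed,
                                       direction=direction)
        marked = apply_thresholds(assocs, table)
        pio.write_association_file(marked, RESULTS / f"associations_{direction}.tsv", dialect)
        pio.write_thresholds(table, RESULTS / f"thresholds_{direction}.tsv")
        n_sig = sum(a.significant for a in marked)
        print(f"{direction}: {len(assocs)} candidate pairs, {n_sig} significant; "
              f"thresholds {table.thresholds}")
        significant |= {(a.go_id, a.umls_cui, direction) for a in marked if a.significant}

    planted = read_planted_links()
    recovered = planted & significant
    print(f"planted process-effect links recovered: {len(recovered)}/{len(planted)}")


if __name__ == "__main__":
    main()
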