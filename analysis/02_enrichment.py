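"""Build the drug -> biological-process layer.

For every (gene set, instance, direction) the running-sum enrichment score is
computed, standardized across instances with the median-MAD robust z-score,
and thresholded: t > 3.0 (about p = 0.001) with gene sets capped at 30
members yields the drug-process edges.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DP_EDGES, SCENARIO_PATHS

from pdsenet import io as pio
from pdsenet.enrichment import compute_es_matrix, filter_edges, median_mad_tscores


def main() -> None:
    matrix = pio.read_rank_matrix(SCENARIO_PATHS["rank_matrix"], SCENARIO_PATHS["metadata"])
    sets = pio.read_gmt(SCENARIO_PATHS["gene_sets"])

    tscores = []
    for direction in ("up", "down"):
        es = compute_es_matrix(matrix, sets, direction)
        ts, stats = median_mad_tscores(es)
        tscores.extend(ts)
        n_deg = sum(s.degenerate for s in stats)
        print(f"{direction}: {len(es)} enrichment scores, "
              f"{len(ts)} t-scores ({n_deg} degenerate rows)")

    edges = filter_edges(tscores, matrix, sets, t_threshold=3.0, max_set_genes=30)
    pio.write_dp_edges(edges, DP_EDGES)
    drugs = {e.drug_name for e in edges}
    print(f"{len(edges)} drug-process edges over {len(drugs)} drugs -> {DP_EDGES}")
    print("top edges by t-score:")
    for e in sorted(edges, key=lambda e: -e.t)[:5]:
        print(f"  {e.drug_name}  {e.go_id} ({e.direction})  t = {e.t:.2f}")


if __name__ == "__main__":
    main()
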