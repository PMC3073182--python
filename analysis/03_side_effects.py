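"""Build the drug -> side-effect layer.

Frequency descriptions are resolved to scores (percentages, ranges, and the
qualitative descriptors of the side-effect source), relations below the 20%
frequency cutoff are dropped, and drug labels are normalized to canonical
drugs through the synonym table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DSE_EDGES, SCENARIO_PATHS

from pdsenet import io as pio
from pdsenet.sider import filter_by_frequency, normalize_drug_names, resolve_frequencies


def main() -> None:
    records = pio.read_side_effects(SCENARIO_PATHS["side_effects"])
    synonyms = pio.read_synonyms(SCENARIO_PATHS["synonyms"])

    resolved = resolve_frequencies(records)
    kept = filter_by_frequency(resolved, min_freq=0.2)
    norm = normalize_drug_names(kept, synonyms)
    pio.write_dse_edges(norm.edges, DSE_EDGES)

    print(f"{len(records)} records; {len(kept)} pass the 20% frequency cutoff; "
          f"{norm.n_unmatched} dropped as unmatched labels")
    drugs = {e.drug_name for e in norm.edges}
    effects = {e.umls_cui for e in norm.edges}
    print(f"{len(norm.edges)} drug-side-effect edges over {len(drugs)} drugs "
          f"and {len(effects)} effects -> {DSE_EDGES}")


if __name__ == "__main__":
    main()
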