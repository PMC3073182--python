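"""Generate the study scenario: a 74-drug, 30-side-effect synthetic dataset.

Emulates the four inputs of the real analysis — a per-instance gene rank
matrix, GO-style gene sets, a SIDER-style side-effect table, and a synonym
table — with planted drug-process perturbations and process-side-effect
links, so later steps can be checked against a known ground truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import GROUNDTRUTH, RESULTS, SCRATCH, SEED

from pdsenet import io as pio
from pdsenet.synthetic import ScenarioConfig, generate_scenario


def main() -> None:
    config = ScenarioConfig(noise_seed=SEED)
    scenario = generate_scenario(config)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    pio.write_scenario(scenario, SCRATCH)
    pio.write_groundtruth(scenario.truth, GROUNDTRUTH)

    truth = scenario.truth
    print(f"scenario written to {SCRATCH} (seed {SEED})")
    print(f"  {config.n_genes} genes x {scenario.rank_matrix.n_instances} instances, "
          f"{config.n_sets} gene sets, {config.n_drugs} drugs, {config.n_effects} effects")
    print(f"  planted: {len(truth.drug_process_plants)} drug-process perturbations, "
          f"{len(truth.process_effect_links)} process-effect links, "
          f"{len(truth.drug_effect_links)} drug-effect links "
          f"(+{len(scenario.side_effects) - len(truth.drug_effect_links)} low-frequency decoys)")
    print(f"ground truth -> {GROUNDTRUTH}")


if __name__ == "__main__":
    main()
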