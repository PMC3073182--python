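import math

import pytest

from pdsenet.enrichment import GeneSet, RankedInstance
from pdsenet.synthetic import ScenarioConfig, generate_scenario


def es_oracle(ordered_genes, members, direction="up"):
    """Exhaustive partial-sum oracle for the enrichment score.

    Evaluates the running sum at every prefix length j = 1..N-1 from its
    closed form (hits*c_hit - misses*c_miss) and returns the maximum
    deviation, clamped at the final value 0.
    """
    order = list(ordered_genes)
    if direction == "down":
        order = order[::-1]
    n = len(order)
    member_set = set(members)
    m = sum(1 for g in order if g in member_set)
    assert 0 < m < n
    c_hit = math.sqrt((n - m) / m)
    c_miss = math.sqrt(m / (n - m))
    best = 0.0
    hits = 0
    for j, g in enumerate(order[:-1], start=1):
        if g in member_set:
            hits += 1
        s = hits * c_hit - (j - hits) * c_miss
        if s > best:
            best = s
    return best


@pytest.fixture
def oracle():
    return es_oracle


def make_instance(n, hit_ranks, instance_id="i1", drug="d1"):
    """Instance over genes g1..gN with set members placed at the given 1-based ranks."""
    genes = [f"g{j}" for j in range(1, n + 1)]
    members = frozenset(genes[r - 1] for r in hit_ranks)
    inst = RankedInstance(instance_id, drug, tuple(genes))
    return inst, GeneSet("GO:0000001", "toy set", members)


@pytest.fixture
def toy_instance():
    return make_instance


SMALL_SCENARIO = ScenarioConfig(
    n_genes=300,
    n_sets=40,
    set_size_range=(5, 15),
    n_drugs=40,
    n_effects=6,
    drugs_per_effect=4,
    n_decoy_links=8,
    noise_seed=11,
)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact seeded scenario shared by the slower integration tests."""
    return generate_scenario(SMALL_SCENARIO)
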