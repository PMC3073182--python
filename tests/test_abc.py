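from collections import Counter

import numpy as np
import pytest

from pdsenet.abc import (
    CoThresholdTable,
    EmptyBridgeError,
    apply_thresholds,
    co_occurrence,
    merge_networks,
    null_distribution,
    permutation_thresholds,
    to_graph,
)
from pdsenet.enrichment import DrugProcessEdge
from pdsenet.sider import DrugSideEffectEdge


def dp(drug, go, direction="up", t=4.0):
    return DrugProcessEdge(drug, go, direction, t, f"{drug}_i1")


def dse(drug, cui, name="effect"):
    return DrugSideEffectEdge("DBX", drug, cui, name, 0.5)


def make_network(dp_map, dse_map):
    """dp_map: drug -> processes; dse_map: cui -> drugs."""
    dp_edges = [dp(d, go) for d, gos in dp_map.items() for go in gos]
    dse_edges = [dse(d, cui) for cui, drugs in dse_map.items() for d in drugs]
    return merge_networks(dp_edges, dse_edges)


class TestMerge:
    def test_bridge_is_intersection(self):
        net = make_network({"a": ["GO:1"], "b": ["GO:1"], "c": ["GO:2"]},
                           {"C1": ["b", "c", "d"]})
        assert net.drugs == {"b", "c"}
        assert all(d in net.drugs for d, *_ in net.dp_edges)

    def test_disjoint_layers_raise(self):
        with pytest.raises(EmptyBridgeError):
            make_network({"a": ["GO:1"]}, {"C1": ["z"]})

    def test_synthetic_bridge_preserves_shared_drugs(self, small_scenario):
        from pdsenet.config import PipelineConfig
        from pdsenet.pipeline import run_from_objects

        sc = small_scenario
        res = run_from_objects(PipelineConfig(n_perm=200, seed=11), sc.rank_matrix,
                               sc.gene_sets, sc.side_effects, sc.synonyms)
        dp_drugs = {e.drug_name for e in res.dp_edges}
        dse_drugs = {e.drug_name for e in res.dse_edges}
        assert res.network.drugs == dp_drugs & dse_drugs


class TestCoOccurrence:
    def test_score_arithmetic(self):
        # 3 of an effect's 10 drugs share the process: score 0.3
        dse_map = {"C0002871": [f"d{k}" for k in range(10)]}
        dp_map = {f"d{k}": ["GO:0016209"] for k in range(3)}
        dp_map.update({f"d{k}": ["GO:9999999"] for k in range(3, 10)})
        net = make_network(dp_map, dse_map)
        assocs = {a.go_id: a for a in co_occurrence(net)}
        a = assocs["GO:0016209"]
        assert (a.cd, a.td) == (3, 10)
        assert a.score == pytest.approx(0.3)

    def test_score_display_rounding_is_presentation_only(self):
        dse_map = {"C0027497": [f"d{k}" for k in range(26)]}
        dp_map = {f"d{k}": ["GO:0019239"] for k in range(5)}
        dp_map.update({f"d{k}": ["GO:8888888"] for k in range(5, 26)})
        net = make_network(dp_map, dse_map)
        a = {x.go_id: x for x in co_occurrence(net)}["GO:0019239"]
        assert a.score == pytest.approx(5 / 26)
        assert round(a.score, 2) == 0.19

    def test_single_drug_effect_excluded(self):
        net = make_network({"a": ["GO:1"], "b": ["GO:1"]}, {"C1": ["a", "b"], "C2": ["a"]})
        assert {a.umls_cui for a in co_occurrence(net)} == {"C1"}

    def test_full_sharing_scores_one(self):
        net = make_network({"a": ["GO:1"], "b": ["GO:1"]}, {"C1": ["a", "b"]})
        (a,) = co_occurrence(net)
        assert a.score == 1.0 and a.cd == a.td == 2

    def test_cd_conservation(self, small_scenario):
        """Per effect, cd summed over processes equals the total hit count."""
        from pdsenet.config import PipelineConfig
        from pdsenet.pipeline import run_from_objects

        sc = small_scenario
        res = run_from_objects(PipelineConfig(n_perm=200, seed=11), sc.rank_matrix,
                               sc.gene_sets, sc.side_effects, sc.synonyms)
        net = res.network
        assocs = co_occurrence(net)
        drug_procs = net.drug_processes()
        for cui, drugs in net.effect_drugs().items():
            if len(drugs) < 2:
                continue
            expected = sum(len(drug_procs.get(d, ())) for d in drugs)
            got = sum(a.cd for a in assocs if a.umls_cui == cui)
            assert got == expected


class TestNullAndThresholds:
    def toy_single_process(self):
        # 4 bridge drugs all hitting the same single process
        return make_network({d: ["GO:1"] for d in "abcd"},
                            {"C1": ["a", "b"], "C2": ["c", "d"]})

    def test_exhaustive_toy_null_is_point_mass(self):
        net = self.toy_single_process()
        null = null_distribution(net, td=2, exhaustive=True)
        assert null == Counter({2: 6})  # C(4,2) draws, always both hit GO:1

    def test_unattainable_threshold_reported(self):
        net = self.toy_single_process()
        table = permutation_thresholds(net, alpha=0.05, exhaustive=True)
        assert table.thresholds == {2: None}
        out = apply_thresholds(co_occurrence(net), table)
        assert out and not any(a.significant for a in out)

    def test_alpha_one_gives_floor(self):
        # null with cd=1 mass: any count >= 2 has tail probability < 1
        net = make_network({"a": ["GO:1"], "b": ["GO:1"], "c": ["GO:2"], "d": ["GO:3"]},
                           {"C1": ["a", "b"], "C2": ["c", "d"]})
        table = permutation_thresholds(net, alpha=1.0, exhaustive=True)
        assert table.thresholds == {2: 2}

    def test_same_seed_same_table(self, small_scenario):
        from pdsenet.config import PipelineConfig
        from pdsenet.pipeline import run_from_objects

        sc = small_scenario
        res = run_from_objects(PipelineConfig(n_perm=100, seed=11), sc.rank_matrix,
                               sc.gene_sets, sc.side_effects, sc.synonyms)
        net = res.network
        t1 = permutation_thresholds(net, n_perm=200, seed=42, direction="up")
        t2 = permutation_thresholds(net, n_perm=200, seed=42, direction="up")
        assert t1.thresholds == t2.thresholds

    def test_td_beyond_pool_rejected(self):
        net = self.toy_single_process()
        with pytest.raises(ValueError, match="exceeds"):
            null_distribution(net, td=99)

    def test_sampled_null_converges_to_exhaustive(self):
        rng = np.random.default_rng(17)
        dp_map = {f"d{k}": [f"GO:{g}" for g in rng.choice(8, size=3, replace=False)]
                  for k in range(6)}
        net = make_network(dp_map, {"C1": ["d0", "d1", "d2"], "C2": ["d3", "d4", "d5"]})
        exact = null_distribution(net, td=2, exhaustive=True)
        sampled = null_distribution(net, td=2, n_perm=10_000,
                                    rng=np.random.default_rng(1))
        p = np.array([exact.get(k, 0) for k in range(1, 7)], dtype=float)
        q = np.array([sampled.get(k, 0) for k in range(1, 7)], dtype=float)
        tv = 0.5 * np.abs(p / p.sum() - q / q.sum()).sum()
        assert tv < 0.05

    def test_thresholds_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        dp_map = {f"d{k}": [f"GO:{g}" for g in rng.choice(10, size=4, replace=False)]
                  for k in range(15)}
        net = make_network(dp_map, {"C1": [f"d{k}" for k in range(6)],
                                    "C2": ["d0", "d1", "d2"]})
        strict = permutation_thresholds(net, n_perm=400, alpha=0.01, seed=5)
        loose = permutation_thresholds(net, n_perm=400, alpha=0.2, seed=5)
        for td in strict.thresholds:
            s, l = strict.thresholds[td], loose.thresholds[td]
            if s is not None and l is not None:
                assert s >= l


class TestApplyThresholds:
    # the published threshold table: 2-5 drugs -> 2, 6-17 -> 3, 19-26 -> 4
    TABLE = CoThresholdTable(
        {**{td: 2 for td in (2, 3, 4, 5)},
         **{td: 3 for td in (6, 7, 8, 9, 10, 11, 12, 14, 15, 16, 17)},
         **{td: 4 for td in (19, 24, 25, 26)}},
        alpha=0.05, n_perm=1000,
    )

    @pytest.mark.parametrize("td,cd,significant", [(4, 2, True), (10, 2, False), (26, 4, True)])
    def test_published_table_semantics(self, td, cd, significant):
        from pdsenet.abc import ProcessEffectAssociation

        a = ProcessEffectAssociation("C1", "GO:1", "up", cd, td, cd / td)
        (out,) = apply_thresholds([a], self.TABLE)
        assert out.significant == significant

    def test_table_shape_non_decreasing(self):
        items = sorted(self.TABLE.thresholds.items())
        values = [v for _, v in items]
        assert values == sorted(values)

    def test_missing_td_entry_rejected(self):
        from pdsenet.abc import ProcessEffectAssociation

        a = ProcessEffectAssociation("C1", "GO:1", "up", 2, 13, 2 / 13)
        with pytest.raises(ValueError, match="td=13"):
            apply_thresholds([a], self.TABLE)

    def test_direction_mismatch_rejected(self):
        from pdsenet.abc import ProcessEffectAssociation

        table = CoThresholdTable({2: 2}, 0.05, 100, direction="up")
        a = ProcessEffectAssociation("C1", "GO:1", "down", 2, 2, 1.0)
        with pytest.raises(ValueError, match="direction"):
            apply_thresholds([a], table)


def test_graph_export_is_tripartite():
    net = make_network({"a": ["GO:1"], "b": ["GO:1", "GO:2"]}, {"C1": ["a", "b"]})
    g = to_graph(net, co_occurrence(net))
    kinds = {data["kind"] for _, data in g.nodes(data=True)}
    assert kinds == {"drug", "process", "effect"}
    layers = {data["layer"] for *_, data in g.edges(data=True)}
    assert layers == {"drug-process", "drug-effect", "process-effect"}
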