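import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdsenet.enrichment import (
    DegenerateSetError,
    GeneSet,
    NoOverlapError,
    EnrichmentScore,
    RankMatrix,
    RankedInstance,
    compute_es,
    compute_es_matrix,
    filter_edges,
    median_mad_tscores,
    running_sum,
)
from conftest import es_oracle


class TestComputeES:
    def test_top_concentrated_pair(self, toy_instance):
        # both members at the very top of a 10-gene list: 2 * sqrt(8/2)
        inst, gs = toy_instance(10, [1, 2])
        assert compute_es(inst, gs, "up").es == pytest.approx(4.0)

    def test_anticorrelated_set_scores_zero(self, toy_instance):
        # members at ranks 2 and 4 of 4: the walk never rises above zero,
        # so the maximum deviation is the final value 0
        inst, gs = toy_instance(4, [2, 4])
        expected = es_oracle(inst.ordered_genes, gs.genes, "up")
        assert expected == 0.0
        assert compute_es(inst, gs, "up").es == expected

    def test_no_overlap_raises(self, toy_instance):
        inst, _ = toy_instance(10, [1])
        alien = GeneSet("GO:0000009", "alien", frozenset(["x1", "x2"]))
        with pytest.raises(NoOverlapError):
            compute_es(inst, alien, "up")

    def test_whole_universe_set_raises(self, toy_instance):
        inst, _ = toy_instance(5, [1])
        full = GeneSet("GO:0000008", "all", frozenset(inst.ordered_genes))
        with pytest.raises(DegenerateSetError):
            compute_es(inst, full, "up")

    def test_es_bounded_by_maximum_concentration(self, toy_instance):
        inst, gs = toy_instance(20, [1, 2, 3, 4])
        m, n = 4, 20
        assert 0.0 <= compute_es(inst, gs, "up").es <= math.sqrt(m * (n - m)) + 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        """The after-hit shortcut equals a scan of every partial sum, N <= 50."""
        n = data.draw(st.integers(min_value=3, max_value=50))
        m = data.draw(st.integers(min_value=1, max_value=n - 1))
        seed = data.draw(st.integers(min_value=0, max_value=2**31 - 1))
        rng = np.random.default_rng(seed)
        genes = [f"g{j}" for j in range(n)]
        order = tuple(rng.permutation(genes))
        members = frozenset(rng.choice(genes, size=m, replace=False))
        inst = RankedInstance("i", "d", order)
        gs = GeneSet("GO:0000001", "t", members)
        direction = data.draw(st.sampled_from(["up", "down"]))
        assert compute_es(inst, gs, direction).es == es_oracle(order, members, direction)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_direction_symmetry(self, seed):
        """Down-direction ES on L equals up-direction ES on reversed L."""
        rng = np.random.default_rng(seed)
        genes = [f"g{j}" for j in range(30)]
        order = tuple(rng.permutation(genes))
        members = frozenset(rng.choice(genes, size=6, replace=False))
        gs = GeneSet("GO:0000001", "t", members)
        fwd = RankedInstance("i", "d", order)
        rev = RankedInstance("i", "d", order[::-1])
        assert compute_es(fwd, gs, "down").es == compute_es(rev, gs, "up").es


class TestRunningSum:
    def test_zero_sum_construction(self, toy_instance):
        inst, gs = toy_instance(25, [3, 7, 20])
        traj = running_sum(inst, gs, "up")
        assert traj.shape == (25,)
        assert abs(traj[-1]) < 1e-9

    def test_es_is_trajectory_maximum(self, toy_instance):
        inst, gs = toy_instance(30, [2, 5, 11, 29])
        traj = running_sum(inst, gs, "up")
        assert compute_es(inst, gs, "up").es == pytest.approx(max(traj.max(), 0.0))


class TestESMatrix:
    def _matrix(self, n_inst=5, n=40, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{j}" for j in range(n)]
        instances = [
            RankedInstance(f"i{k}", f"d{k % 3}", tuple(rng.permutation(genes)))
            for k in range(n_inst)
        ]
        return RankMatrix(instances), genes, rng

    def test_cardinality_and_elementwise_match(self):
        matrix, genes, rng = self._matrix()
        sets = [
            GeneSet(f"GO:{i:07d}", "t", frozenset(rng.choice(genes, size=5, replace=False)))
            for i in range(1, 11)
        ]
        scores = compute_es_matrix(matrix, sets, "up")
        assert len(scores) == 50
        by_pair = {(s.go_id, s.instance_id): s.es for s in scores}
        for inst in matrix.instances:
            for gs in sets:
                assert by_pair[(gs.go_id, inst.instance_id)] == compute_es(inst, gs, "up").es

    def test_no_overlap_set_skipped_not_fatal(self, caplog):
        matrix, genes, rng = self._matrix()
        sets = [
            GeneSet("GO:0000001", "ok", frozenset(genes[:4])),
            GeneSet("GO:0000002", "alien", frozenset(["zz1", "zz2"])),
        ]
        with caplog.at_level("WARNING"):
            scores = compute_es_matrix(matrix, sets, "up")
        assert len(scores) == 5
        assert any("GO:0000002" in r.message for r in caplog.records)

    def test_empty_inputs_rejected(self):
        matrix, genes, _ = self._matrix()
        with pytest.raises(ValueError):
            compute_es_matrix(matrix, [], "up")


class TestMedianMadTScores:
    @staticmethod
    def _row(values, go_id="GO:0000001", direction="up"):
        return [EnrichmentScore(go_id, f"i{k}", direction, v) for k, v in enumerate(values)]

    def test_outlier_row(self):
        # median 3, MAD 1: the outlier scores (100-3)/(1.4826*1)
        ts, stats = median_mad_tscores(self._row([1, 2, 3, 4, 100]))
        t_by_inst = {t.instance_id: t.t for t in ts}
        assert t_by_inst["i4"] == pytest.approx(97 / 1.4826, abs=1e-9)
        assert stats[0].median == 3 and stats[0].mad == 1

    def test_symmetric_row(self):
        ts, _ = median_mad_tscores(self._row([-1, 0, 1]))
        t_by_inst = {t.instance_id: t.t for t in ts}
        assert t_by_inst["i2"] == pytest.approx(1 / 1.4826)

    def test_constant_row_degenerate(self):
        ts, stats = median_mad_tscores(self._row([2, 2, 2]))
        assert ts == []
        assert stats[0].degenerate

    def test_single_instance_group_rejected(self):
        with pytest.raises(ValueError, match="need >= 2"):
            median_mad_tscores(self._row([1.0]))

    def test_scale_invariance(self):
        """Multiplying a row by any positive constant leaves t-scores unchanged."""
        rng = np.random.default_rng(5)
        values = rng.normal(10, 3, size=20)
        base, _ = median_mad_tscores(self._row(values))
        for c in (0.25, 7.0, 1e3):
            scaled, _ = median_mad_tscores(self._row(values * c))
            for a, b in zip(base, scaled):
                assert b.t == pytest.approx(a.t, abs=1e-9)


class TestFilterEdges:
    def _setup(self, set_size):
        rng = np.random.default_rng(2)
        genes = [f"g{j}" for j in range(60)]
        inst = RankedInstance("i0", "drugA", tuple(rng.permutation(genes)))
        matrix = RankMatrix([inst])
        gs = GeneSet("GO:0000001", "t", frozenset(genes[:set_size]))
        return matrix, [gs]

    @pytest.mark.parametrize(
        "t,size,kept",
        [
            (3.01, 30, True),  # strict inequality on t, inclusive 30-gene cap
            (4.14835, 30, True),
            (3.0, 30, False),
            (3.5, 31, False),  # "less than 31 genes"
        ],
    )
    def test_thresholds(self, t, size, kept):
        from pdsenet.enrichment import ProcessTScore

        matrix, sets = self._setup(size)
        edges = filter_edges([ProcessTScore("GO:0000001", "i0", "up", t)], matrix, sets)
        assert (len(edges) == 1) == kept
        if kept:
            assert edges[0].drug_name == "drugA"

    def test_max_t_aggregation_keeps_best_instance(self):
        from pdsenet.enrichment import ProcessTScore

        rng = np.random.default_rng(3)
        genes = [f"g{j}" for j in range(40)]
        instances = [
            RankedInstance(f"i{k}", "drugA", tuple(rng.permutation(genes))) for k in range(3)
        ]
        matrix = RankMatrix(instances)
        sets = [GeneSet("GO:0000001", "t", frozenset(genes[:5]))]
        ts = [ProcessTScore("GO:0000001", f"i{k}", "up", 3.0 + k) for k in range(3)]
        union = filter_edges(ts, matrix, sets, aggregation="union")
        best = filter_edges(ts, matrix, sets, aggregation="max_t")
        assert len(union) == 2 and len(best) == 1
        assert best[0].instance_id == "i2" and best[0].t == pytest.approx(5.0)
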