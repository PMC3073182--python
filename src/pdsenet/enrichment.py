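"""Rank-based gene-set enrichment and the drug -> biological-process layer.

A drug-treatment *instance* is a total ordering of the gene (probe) universe,
ranked by the treatment-to-control expression ratio: genes near the top are
up-regulated by the drug, genes near the bottom down-regulated.  For each
GO-style gene set we walk the ranked list with a zero-sum running statistic
(the classic unweighted Kolmogorov-Smirnov-style enrichment score): every set
member adds ``sqrt((N - N_s)/N_s)``, every non-member subtracts
``sqrt(N_s/(N - N_s))``, so the sum returns to zero exactly at the end of the
list.  The enrichment score (ES) is the maximum deviation from zero reached
by the running sum — its running maximum over the walk, which is never below
the final value 0.  A set whose members pile up at the top of the list scores
highly; a set at the bottom scores 0.

Down-regulation is scored by walking the *reversed* list (this is why the
maximum, not the extremum of either sign, is the score: bottom-concentration
is detected by re-walking from the other end), so a set concentrated at the
bottom of the original ranking yields a large ES in the ``down`` direction.

Across many instances, per-set ES values are standardized robustly: with the
per-(set, direction) median MED and median absolute deviation MAD, the score

    t = (ES - MED) / (1.4826 * MAD)

behaves like a z-score when the bulk of instances is null (1.4826 * MAD is a
consistent estimator of sigma under normality), and an instance whose t
exceeds a threshold (3.0 by default, roughly p = 0.001) contributes a
drug -> process edge.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Direction",
    "MAD_SCALE",
    "GeneSet",
    "RankedInstance",
    "RankMatrix",
    "EnrichmentScore",
    "RobustRowStats",
    "ProcessTScore",
    "DrugProcessEdge",
    "NoOverlapError",
    "DegenerateSetError",
    "compute_es",
    "running_sum",
    "compute_es_matrix",
    "median_mad_tscores",
    "filter_edges",
]

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]

#: Scale factor making the median absolute deviation a consistent estimator of
#: the standard deviation under normality (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826


class NoOverlapError(ValueError):
    """A gene set shares no member with the instance's gene universe."""


class DegenerateSetError(ValueError):
    """A gene set covers the whole universe, leaving the miss increment undefined."""


@dataclass(frozen=True)
class GeneSet:
    """A GO-style term with its member genes (the set S, size N_s)."""

    go_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.go_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RankedInstance:
    """One treatment instance's total ordering of the gene universe.

    ``ordered_genes[j]`` is the gene at rank j+1, i.e. position 0 holds the
    most up-regulated gene.
    """

    instance_id: str
    drug_name: str
    ordered_genes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "ordered_genes", tuple(self.ordered_genes))
        n = len(self.ordered_genes)
        if n < 2:
            raise ValueError(f"instance {self.instance_id!r}: need at least 2 genes, got {n}")
        if len(set(self.ordered_genes)) != n:
            raise ValueError(f"instance {self.instance_id!r}: duplicate genes in ranked list")

    @property
    def n_genes(self) -> int:
        return len(self.ordered_genes)


@dataclass
class RankMatrix:
    """A collection of ranked instances over a shared gene universe."""

    instances: list
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe and self.instances:
            self.universe = frozenset(self.instances[0].ordered_genes)
        for inst in self.instances:
            if frozenset(inst.ordered_genes) != self.universe:
                raise ValueError(
                    f"instance {inst.instance_id!r} is not a permutation of the shared universe"
                )

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def drug_of(self) -> dict:
        return {inst.instance_id: inst.drug_name for inst in self.instances}


@dataclass(frozen=True)
class EnrichmentScore:
    go_id: str
    instance_id: str
    direction: str
    es: float


@dataclass(frozen=True)
class RobustRowStats:
    """Median / MAD of one (gene set, direction) row across instances."""

    go_id: str
    direction: str
    median: float
    mad: float
    n_samples: int

    @property
    def degenerate(self) -> bool:
        return self.mad == 0.0


@dataclass(frozen=True)
class ProcessTScore:
    go_id: str
    instance_id: str
    direction: str
    t: float


@dataclass(frozen=True)
class DrugProcessEdge:
    drug_name: str
    go_id: str
    direction: str
    t: float
    instance_id: str


def _es_from_positions(hit_pos: np.ndarray, n: int) -> float:
    """Running-sum maximum given 0-based member positions in walk order.

    The running sum is strictly decreasing between hits, so its local maxima
    occur immediately after a hit; the walk also ends at exactly 0, so the
    overall maximum deviation is ``max(0, max over hits)``.
    """
    m = int(hit_pos.size)
    if m == 0:
        raise NoOverlapError("gene set has no overlap with the ranked list")
    if m >= n:
        raise DegenerateSetError("gene set covers the entire universe")
    c_hit = math.sqrt((n - m) / m)
    c_miss = math.sqrt(m / (n - m))
    p = np.sort(np.asarray(hit_pos, dtype=np.int64))
    ks = np.arange(1, m + 1, dtype=np.float64)
    # value at 1-based position p+1 (just after the k-th hit); position N is
    # excluded — the walk ends there at exactly 0, which the clamp supplies
    interior = p < n - 1
    if not interior.any():
        return 0.0
    after = ks[interior] * c_hit - (p[interior] + 1 - ks[interior]) * c_miss
    return max(0.0, float(np.max(after)))


def _hit_positions(instance: RankedInstance, gene_set: GeneSet, direction: str) -> np.ndarray:
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    order = instance.ordered_genes
    n = len(order)
    index = {g: i for i, g in enumerate(order)}
    pos = [index[g] for g in gene_set.genes if g in index]
    pos_arr = np.asarray(sorted(pos), dtype=np.int64)
    if direction == "down":
        pos_arr = np.sort(n - 1 - pos_arr)
    return pos_arr


def compute_es(instance: RankedInstance, gene_set: GeneSet, direction: str = "up") -> EnrichmentScore:
    """Enrichment score of one gene set in one ranked instance.

    Raises :class:`NoOverlapError` if the set shares no gene with the
    instance's universe, and :class:`DegenerateSetError` if it covers all of
    it (the miss increment would be undefined).
    """
    pos = _hit_positions(instance, gene_set, direction)
    es = _es_from_positions(pos, instance.n_genes)
    return EnrichmentScore(gene_set.go_id, instance.instance_id, direction, es)


def running_sum(instance: RankedInstance, gene_set: GeneSet, direction: str = "up") -> np.ndarray:
    """Full running-sum trajectory (length N) of the enrichment walk.

    Mostly a diagnostic: the last element is 0 up to rounding, by the
    zero-sum construction of the increments.
    """
    pos = _hit_positions(instance, gene_set, direction)
    n = instance.n_genes
    m = pos.size
    if m == 0:
        raise NoOverlapError("gene set has no overlap with the ranked list")
    if m >= n:
        raise DegenerateSetError("gene set covers the entire universe")
    incr = np.full(n, -math.sqrt(m / (n - m)))
    incr[pos] = math.sqrt((n - m) / m)
    return np.cumsum(incr)


def compute_es_matrix(
    matrix: RankMatrix, sets: Sequence[GeneSet], direction: str = "up"
) -> list:
    """ES for every (gene set, instance) pair in one direction.

    Sets that fail the per-pair preconditions (no overlap, whole-universe)
    are skipped with a warning rather than aborting the run.
    """
    if not matrix.instances or not sets:
        raise ValueError("compute_es_matrix needs a nonempty matrix and nonempty set list")
    n = matrix.n_genes
    scores: list = []
    skipped: set = set()
    for inst in matrix.instances:
        order = inst.ordered_genes
        index = {g: i for i, g in enumerate(order)}
        for gs in sets:
            pos = sorted(index[g] for g in gs.genes if g in index)
            if not pos or len(pos) >= n:
                skipped.add(gs.go_id)
                continue
            pos_arr = np.asarray(pos, dtype=np.int64)
            if direction == "down":
                pos_arr = np.sort(n - 1 - pos_arr)
            es = _es_from_positions(pos_arr, n)
            scores.append(EnrichmentScore(gs.go_id, inst.instance_id, direction, es))
    for go_id in sorted(skipped):
        logger.warning("gene set %s skipped: no usable overlap with the rank matrix", go_id)
    return scores


def median_mad_tscores(scores: Iterable[EnrichmentScore]):
    """Robust per-(set, direction) standardization of enrichment scores.

    Returns ``(tscores, row_stats)``.  Rows with MAD = 0 (constant ES across
    instances) are flagged degenerate and emit no t-scores instead of
    infinite ones.
    """
    groups: dict = defaultdict(list)
    for s in scores:
        groups[(s.go_id, s.direction)].append(s)
    tscores: list = []
    stats: list = []
    for (go_id, direction) in sorted(groups):
        members = groups[(go_id, direction)]
        if len(members) < 2:
            raise ValueError(
                f"group ({go_id}, {direction}) has {len(members)} instance(s); need >= 2"
            )
        es = np.array([m.es for m in members])
        med = float(np.median(es))
        mad = float(np.median(np.abs(es - med)))
        stats.append(RobustRowStats(go_id, direction, med, mad, len(members)))
        if mad == 0.0:
            logger.warning("row (%s, %s) has MAD = 0; excluded from t-scores", go_id, direction)
            continue
        scale = MAD_SCALE * mad
        for m in members:
            tscores.append(ProcessTScore(go_id, m.instance_id, direction, (m.es - med) / scale))
    return tscores, stats


def filter_edges(
    tscores: Iterable[ProcessTScore],
    matrix: RankMatrix,
    sets: Sequence[GeneSet],
    t_threshold: float = 3.0,
    max_set_genes: int = 30,
    aggregation: str = "union",
) -> list:
    """Threshold t-scores into drug -> process edges.

    Keeps pairs with ``t > t_threshold`` (strict) whose set has at most
    ``max_set_genes`` members in the matrix universe ("less than 31 genes").
    ``aggregation='union'`` keeps one edge per passing instance;
    ``aggregation='max_t'`` keeps only the best-scoring instance per
    (drug, process, direction).
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    if aggregation not in ("union", "max_t"):
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    universe = matrix.universe
    set_sizes = {gs.go_id: len(gs.genes & universe) for gs in sets}
    drug_of = matrix.drug_of()
    edges: list = []
    for ts in tscores:
        size = set_sizes.get(ts.go_id)
        if size is None or size > max_set_genes:
            continue
        if not ts.t > t_threshold:
            continue
        drug = drug_of.get(ts.instance_id)
        if drug is None:
            raise ValueError(f"t-score references unknown instance {ts.instance_id!r}")
        edges.append(DrugProcessEdge(drug, ts.go_id, ts.direction, ts.t, ts.instance_id))
    if aggregation == "max_t":
        best: dict = {}
        for e in edges:
            key = (e.drug_name, e.go_id, e.direction)
            if key not in best or e.t > best[key].t:
                best[key] = e
        edges = list(best.values())
    edges.sort(key=lambda e: (e.drug_name, e.go_id, e.direction, e.instance_id))
    return edges
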