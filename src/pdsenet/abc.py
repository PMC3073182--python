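"""ABC co-occurrence model: processes (A) - drugs (B) - side effects (C).

The drug -> process layer and the drug -> side-effect layer are merged over
the drugs present in both; those bridge drugs connect each side effect to the
biological processes its drugs perturb.  For a side effect j caused by TD_j
bridge drugs, a process i hit by CD_ij of them gets the co-occurrence score

    Score_ij = CD_ij / TD_j,

the fraction of the effect's drugs that share the process.  Effects with
fewer than two drugs carry no co-occurrence evidence and are excluded.

Significance comes from a permutation null: for each observed drug count TD,
TD drugs are drawn uniformly without replacement from the bridge pool many
times, per-process co-occurrence counts are recomputed against the *real*
drug -> process layer, and the counts (pooled across processes within the TD
group) form the null distribution.  The significance threshold for TD is the
smallest count whose null tail probability falls below alpha — one threshold
per TD, non-decreasing in TD.  Up- and down-regulated process layers are
scored independently end-to-end.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ABCNetwork",
    "ProcessEffectAssociation",
    "CoThresholdTable",
    "EmptyBridgeError",
    "merge_networks",
    "co_occurrence",
    "null_distribution",
    "permutation_thresholds",
    "apply_thresholds",
    "to_graph",
]

logger = logging.getLogger(__name__)


class EmptyBridgeError(ValueError):
    """No drug appears in both the process layer and the side-effect layer."""


@dataclass
class ABCNetwork:
    """Tripartite network restricted to the bridge drugs.

    ``dp_edges`` holds (drug, go_id, direction) triples, ``dse_edges``
    (drug, umls_cui) pairs; every endpoint drug is a bridge drug.
    """

    drugs: frozenset
    dp_edges: frozenset
    dse_edges: frozenset
    effect_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d, *_ in self.dp_edges:
            if d not in self.drugs:
                raise ValueError(f"process-layer drug {d!r} outside the bridge")
        for d, _ in self.dse_edges:
            if d not in self.drugs:
                raise ValueError(f"side-effect-layer drug {d!r} outside the bridge")

    @property
    def processes(self) -> frozenset:
        return frozenset((go, direction) for _, go, direction in self.dp_edges)

    @property
    def effects(self) -> frozenset:
        return frozenset(cui for _, cui in self.dse_edges)

    def effect_drugs(self) -> dict:
        out: dict = defaultdict(set)
        for d, cui in self.dse_edges:
            out[cui].add(d)
        return dict(out)

    def drug_processes(self, direction: Optional[str] = None) -> dict:
        out: dict = defaultdict(set)
        for d, go, dr in self.dp_edges:
            if direction is None or dr == direction:
                out[d].add((go, dr))
        return dict(out)

    def summary(self) -> dict:
        return {
            "n_drugs": len(self.drugs),
            "n_effects": len(self.effects),
            "n_processes": len(self.processes),
            "n_dp_edges": len(self.dp_edges),
            "n_dse_edges": len(self.dse_edges),
        }


@dataclass(frozen=True)
class ProcessEffectAssociation:
    """One (side effect, process) pair with its co-occurrence evidence."""

    umls_cui: str
    go_id: str
    direction: str
    cd: int
    td: int
    score: float
    significant: bool = False
    effect_name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.cd <= self.td:
            raise ValueError(f"cd={self.cd} outside [0, td={self.td}]")
        if self.td < 2:
            raise ValueError(f"td={self.td} < 2: effect carries no co-occurrence evidence")


@dataclass
class CoThresholdTable:
    """Minimal significant co-occurrence count per observed drug count (TD).

    A ``None`` threshold marks a TD whose null never drops below alpha
    (no count is significant at that level).
    """

    thresholds: dict  # td -> Optional[int]
    alpha: float
    n_perm: int
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        for td, thr in self.thresholds.items():
            if thr is not None and thr < 2:
                raise ValueError(f"threshold {thr} for td={td} below the floor of 2")


def merge_networks(dp_edges: Sequence, dse_edges: Sequence) -> ABCNetwork:
    """Restrict both layers to drugs present in each (the ABC bridge)."""
    dp_drugs = {e.drug_name for e in dp_edges}
    dse_drugs = {e.drug_name for e in dse_edges}
    bridge = dp_drugs & dse_drugs
    if not bridge:
        raise EmptyBridgeError(
            f"no shared drugs: {len(dp_drugs)} process-layer vs {len(dse_drugs)} "
            "side-effect-layer drugs are disjoint"
        )
    dp = frozenset((e.drug_name, e.go_id, e.direction) for e in dp_edges if e.drug_name in bridge)
    dse = frozenset((e.drug_name, e.umls_cui) for e in dse_edges if e.drug_name in bridge)
    names = {e.umls_cui: e.effect_name for e in dse_edges if e.drug_name in bridge}
    net = ABCNetwork(frozenset(bridge), dp, dse, names)
    logger.info("merged network: %s", net.summary())
    return net


def co_occurrence(
    network: ABCNetwork,
    min_drugs: int = 2,
    direction: Optional[str] = None,
) -> list:
    """Score every (effect, process) candidate pair by CD/TD.

    Effects with fewer than ``min_drugs`` drugs are excluded entirely; a
    process enters an effect's candidate list as soon as one of the effect's
    drugs hits it.  Scores are exact ratios — any rounding is presentation.
    """
    if min_drugs < 2:
        raise ValueError("min_drugs must be >= 2")
    drug_procs = network.drug_processes(direction)
    assocs: list = []
    for cui, drugs in sorted(network.effect_drugs().items()):
        td = len(drugs)
        if td < min_drugs:
            continue
        counts: Counter = Counter()
        for d in drugs:
            counts.update(drug_procs.get(d, ()))
        for (go, dr), cd in sorted(counts.items()):
            assocs.append(
                ProcessEffectAssociation(
                    cui, go, dr, cd, td, cd / td,
                    effect_name=network.effect_names.get(cui, ""),
                )
            )
    return assocs


def _dp_matrix(network: ABCNetwork, direction: Optional[str]):
    """Boolean drug x process incidence matrix of the real process layer."""
    drugs = sorted(network.drugs)
    procs = sorted(network.processes if direction is None
                   else {p for p in network.processes if p[1] == direction})
    drug_ix = {d: i for i, d in enumerate(drugs)}
    proc_ix = {p: j for j, p in enumerate(procs)}
    mat = np.zeros((len(drugs), len(procs)), dtype=bool)
    for d, go, dr in network.dp_edges:
        if (go, dr) in proc_ix:
            mat[drug_ix[d], proc_ix[(go, dr)]] = True
    return mat, drugs, procs


def null_distribution(
    network: ABCNetwork,
    td: int,
    direction: Optional[str] = None,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    exhaustive: bool = False,
) -> Counter:
    """Pooled null distribution of co-occurrence counts for one TD.

    Draws ``td`` drugs without replacement from the bridge pool (or, with
    ``exhaustive=True``, enumerates every combination), recomputes per-process
    counts against the real drug -> process layer, and pools the nonzero
    counts across processes and draws.
    """
    mat, drugs, _ = _dp_matrix(network, direction)
    n = len(drugs)
    if td > n:
        raise ValueError(f"td={td} exceeds the bridge pool of {n} drugs")
    if td < 1:
        raise ValueError("td must be >= 1")
    null: Counter = Counter()
    if exhaustive:
        for combo in itertools.combinations(range(n), td):
            counts = mat[list(combo)].sum(axis=0)
            null.update(counts[counts > 0].tolist())
    else:
        if rng is None:
            rng = np.random.default_rng()
        for _ in range(n_perm):
            idx = rng.choice(n, size=td, replace=False)
            counts = mat[idx].sum(axis=0)
            null.update(counts[counts > 0].tolist())
    return null


def _threshold_from_null(null: Counter, alpha: float, plus_one: bool) -> Optional[int]:
    total = sum(null.values())
    if total == 0:
        return None
    max_cd = max(null)
    for c in range(2, max_cd + 1):
        tail = sum(v for k, v in null.items() if k >= c)
        p = (tail + 1) / (total + 1) if plus_one else tail / total
        if p < alpha:
            return c
    return None


def permutation_thresholds(
    network: ABCNetwork,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    direction: Optional[str] = None,
    min_drugs: int = 2,
    plus_one: bool = False,
    exhaustive: bool = False,
) -> CoThresholdTable:
    """Permutation significance thresholds for every observed TD.

    The threshold for a TD is the smallest count c >= 2 whose pooled null
    tail probability P(null >= c) is strictly below alpha (``plus_one`` adds
    the conventional +1 correction to numerator and denominator).  Identical
    seed gives an identical table.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    tds = sorted({len(d) for d in network.effect_drugs().values() if len(d) >= min_drugs})
    rng = np.random.default_rng(seed)
    thresholds: dict = {}
    for td in tds:
        null = null_distribution(network, td, direction, n_perm, rng, exhaustive)
        thresholds[td] = _threshold_from_null(null, alpha, plus_one)
        if thresholds[td] is None:
            logger.warning("td=%d: no co-occurrence count reaches p < %g", td, alpha)
    return CoThresholdTable(thresholds, alpha, n_perm, direction)


def apply_thresholds(
    assocs: Iterable[ProcessEffectAssociation],
    table: CoThresholdTable,
) -> list:
    """Mark each association significant when its CD clears its TD's threshold."""
    out: list = []
    for a in assocs:
        if table.direction is not None and a.direction != table.direction:
            raise ValueError(
                f"association direction {a.direction!r} does not match table "
                f"direction {table.direction!r}"
            )
        if a.td not in table.thresholds:
            raise ValueError(f"no threshold entry for td={a.td}")
        thr = table.thresholds[a.td]
        out.append(replace(a, significant=thr is not None and a.cd >= thr))
    return out


def to_graph(network: ABCNetwork, assocs: Optional[Iterable[ProcessEffectAssociation]] = None):
    """Tripartite process-drug-side-effect graph (for GraphML export)."""
    g = nx.Graph()
    for d in sorted(network.drugs):
        g.add_node(f"drug:{d}", kind="drug", label=d)
    for go, direction in sorted(network.processes):
        g.add_node(f"process:{go}:{direction}", kind="process", label=go, direction=direction)
    for cui in sorted(network.effects):
        g.add_node(f"effect:{cui}", kind="effect", label=cui,
                   name=network.effect_names.get(cui, ""))
    for d, go, direction in sorted(network.dp_edges):
        g.add_edge(f"drug:{d}", f"process:{go}:{direction}", layer="drug-process")
    for d, cui in sorted(network.dse_edges):
        g.add_edge(f"drug:{d}", f"effect:{cui}", layer="drug-effect")
    if assocs is not None:
        for a in assocs:
            g.add_edge(
                f"process:{a.go_id}:{a.direction}", f"effect:{a.umls_cui}",
                layer="process-effect", cd=a.cd, td=a.td, score=a.score,
                significant=bool(a.significant),
            )
    return g
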