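"""Synthetic scenarios with known ground truth for the whole pipeline.

A scenario emulates the four inputs the pipeline consumes — a per-instance
gene rank matrix, GO-style gene sets, a SIDER-style side-effect table, and a
DrugBank-style synonym table — at desk scale, with *planted* structure:

* selected (drug, gene set, direction) triples are perturbed by forcing a
  fraction of the set's genes into the top (up) or bottom (down) decile of
  that drug's ranked list, at uniformly random positions within the decile;
  every other rank is uniformly random;
* drugs sharing a planted side effect share the planted process responsible
  for it, so the end-to-end co-occurrence analysis has a recoverable signal;
* planted drug - side-effect links carry frequency scores above the 20%
  filter ({25%, 50%, 75%}); decoy links carry scores below it.

The decile placement is an artifact of this generator, not a claim about real
drug-response effect sizes: it makes the enrichment score of a planted set
large while keeping the running-sum statistic well defined.  All randomness
derives from one seed sequence, forked per sub-generator, so e.g. adding
drugs does not reshuffle the gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .enrichment import GeneSet, RankMatrix, RankedInstance
from .sider import SideEffectRecord, SynonymTable

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_scenario",
    "make_synonym_collisions",
]

#: Frequency scores for planted drug - side-effect links (all pass the 20% filter)
PLANTED_FREQS = (0.25, 0.5, 0.75)
#: Frequency scores for decoy links (all fail the 20% filter)
DECOY_FREQS = (0.001, 0.01, 0.1)

_FREQ_DESCRIPTIONS = {
    0.25: "25%",
    0.5: "50%",
    0.75: "75%",
    0.001: "Rare",
    0.01: "Infrequent",
    0.1: "10%",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Dimensions and effect strength of a synthetic scenario.

    Defaults mirror the scale of the merged real network (74 bridge drugs)
    with a reduced gene universe and gene-set catalogue.
    """

    n_genes: int = 2000
    n_sets: int = 200
    set_size_range: Tuple[int, int] = (5, 30)
    n_drugs: int = 74
    n_effects: int = 30
    instances_per_drug: int = 1
    planted_strength: float = 0.8
    drugs_per_effect: int = 4
    n_decoy_links: int = 30
    min_planted_set_size: int = 8
    noise_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi < self.n_genes):
            raise ValueError(f"set_size_range {self.set_size_range} invalid for {self.n_genes} genes")
        for name in ("n_genes", "n_sets", "n_drugs", "n_effects", "instances_per_drug"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.planted_strength <= 1.0:
            raise ValueError("planted_strength must be in [0, 1]")
        if self.n_effects > self.n_sets:
            raise ValueError("need at least one gene set per planted effect")
        if self.drugs_per_effect > self.n_drugs:
            raise ValueError("drugs_per_effect exceeds n_drugs")


@dataclass
class GroundTruth:
    """Planted structure of a scenario, for recovery checks."""

    drug_process_plants: set = field(default_factory=set)  # (drug, go_id, direction)
    process_effect_links: set = field(default_factory=set)  # (go_id, umls_cui, direction)
    drug_effect_links: dict = field(default_factory=dict)  # (drug, umls_cui) -> freq score


class Scenario(NamedTuple):
    rank_matrix: RankMatrix
    gene_sets: list
    side_effects: list
    synonyms: SynonymTable
    truth: GroundTruth


def _decile(n_genes: int) -> int:
    return max(1, n_genes // 10)


_TERM_NOUNS = ("lipid", "sterol", "peptide", "cytokine", "nucleotide", "hexose",
               "actin", "collagen", "histone", "ubiquitin", "glycogen", "heme",
               "retinol", "folate", "pyruvate", "lactate", "chitin", "melanin",
               "urea", "calcium", "keratin", "elastin", "fibrin", "mucin",
               "tubulin", "myosin", "laminin", "insulin", "gastrin", "leptin",
               "serotonin", "dopamine", "cortisol", "glucagon", "thrombin",
               "pepsin", "amylase", "lipase", "catalase", "ferritin")
_TERM_TAILS = ("flux", "repair", "assembly", "export", "uptake", "turnover",
               "fusion", "decay", "signaling", "storage", "cleavage", "docking")


def _term_names(n: int, rng) -> list:
    """Distinct GO-style term names, preferring mutually dissimilar ones.

    Normalized edit distance treats names sharing a long scaffold as near
    matches, so names are greedily selected to keep pairwise similarity below
    the 0.55 matching threshold where the vocabulary allows it.
    """
    from .litmatch import string_similarity

    combos = [f"{a} {b} {tail}"
              for a in _TERM_NOUNS for b in _TERM_NOUNS if a != b
              for tail in _TERM_TAILS]
    order = rng.permutation(len(combos))
    kept: list = []
    spare: list = []
    for ix in order:
        c = combos[int(ix)]
        if len(kept) >= n:
            break
        if all(string_similarity(c, k) < 0.55 for k in kept):
            kept.append(c)
        else:
            spare.append(c)
    while len(kept) < n:  # vocabulary exhausted: fall back to similar names
        kept.append(spare.pop(0))
    return kept


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate one complete scenario; identical config gives identical output."""
    ss = np.random.SeedSequence(config.noise_seed)
    c_sets, c_truth, c_ranks, c_fx = ss.spawn(4)
    sets_rng = np.random.default_rng(c_sets)
    truth_rng = np.random.default_rng(c_truth)
    fx_rng = np.random.default_rng(c_fx)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    drugs = [f"drug{i + 1:03d}" for i in range(config.n_drugs)]
    cuis = [f"C{1000000 + i}" for i in range(config.n_effects)]
    effect_names = {cui: f"effect_{i + 1:02d}" for i, cui in enumerate(cuis)}

    lo, hi = config.set_size_range
    term_names = _term_names(config.n_sets, sets_rng)
    gene_sets = []
    for i in range(config.n_sets):
        size = int(sets_rng.integers(lo, hi + 1))
        members = sets_rng.choice(config.n_genes, size=size, replace=False)
        gene_sets.append(
            GeneSet(f"GO:{i + 1:07d}", term_names[i],
                    frozenset(genes[j] for j in members))
        )

    truth = GroundTruth()
    # plant only in sets the enrichment statistic has power to detect at the
    # configured strength: a 4-gene signal in the decile sits right at the
    # null's 3-sigma boundary, larger sets clear it comfortably
    eligible = np.array([i for i, gs in enumerate(gene_sets)
                         if gs.size >= config.min_planted_set_size])
    if eligible.size < config.n_effects:
        raise ValueError(
            f"only {eligible.size} gene sets of size >= {config.min_planted_set_size} "
            f"available for {config.n_effects} planted effects"
        )
    planted_set_ix = eligible[
        truth_rng.choice(eligible.size, size=config.n_effects, replace=False)
    ]
    for cui, set_ix in zip(cuis, planted_set_ix):
        gs = gene_sets[int(set_ix)]
        direction = "up" if truth_rng.random() < 0.5 else "down"
        group = truth_rng.choice(config.n_drugs, size=config.drugs_per_effect, replace=False)
        truth.process_effect_links.add((gs.go_id, cui, direction))
        for d_ix in group:
            drug = drugs[int(d_ix)]
            truth.drug_process_plants.add((drug, gs.go_id, direction))
            freq = float(truth_rng.choice(PLANTED_FREQS))
            truth.drug_effect_links[(drug, cui)] = freq

    set_by_id = {gs.go_id: gs for gs in gene_sets}
    plants_by_drug: dict = {d: [] for d in drugs}
    for drug, go_id, direction in sorted(truth.drug_process_plants):
        plants_by_drug[drug].append((go_id, direction))

    instances = []
    rank_children = c_ranks.spawn(config.n_drugs * config.instances_per_drug)
    child_ix = 0
    for drug in drugs:
        for k in range(config.instances_per_drug):
            rng = np.random.default_rng(rank_children[child_ix])
            child_ix += 1
            order = _plant_column(config, genes, plants_by_drug[drug], set_by_id, rng)
            instances.append(RankedInstance(f"{drug}_i{k + 1}", drug, order))
    matrix = RankMatrix(instances, frozenset(genes))

    synonyms = SynonymTable()
    for i, drug in enumerate(drugs):
        cid = f"DB{i + 1:05d}"
        synonyms.add(cid, drug, "primary")
        synonyms.add(cid, f"{drug}-syn", "synonym")
        synonyms.add(cid, f"Brand{i + 1:03d}", "brand")

    records = []
    for (drug, cui), freq in sorted(truth.drug_effect_links.items()):
        records.append(
            SideEffectRecord(drug, cui, effect_names[cui], _FREQ_DESCRIPTIONS[freq], freq)
        )
    planted_pairs = set(truth.drug_effect_links)
    n_available = config.n_drugs * config.n_effects - len(planted_pairs)
    n_decoys = 0
    while n_decoys < min(config.n_decoy_links, n_available):
        drug = drugs[int(fx_rng.integers(config.n_drugs))]
        cui = cuis[int(fx_rng.integers(config.n_effects))]
        if (drug, cui) in planted_pairs:
            continue
        planted_pairs.add((drug, cui))
        freq = float(fx_rng.choice(DECOY_FREQS))
        records.append(
            SideEffectRecord(drug, cui, effect_names[cui], _FREQ_DESCRIPTIONS[freq], freq)
        )
        n_decoys += 1
    records.sort(key=lambda r: (r.compound_id, r.umls_cui))

    return Scenario(matrix, gene_sets, records, synonyms, truth)


def _plant_column(config, genes, plants, set_by_id, rng) -> tuple:
    """One ranked column: planted genes in their decile, the rest uniform."""
    n = config.n_genes
    decile = _decile(n)
    zone_of: dict = {}
    for go_id, direction in plants:
        members = sorted(set_by_id[go_id].genes)
        k = int(round(config.planted_strength * len(members)))
        if k == 0:
            continue
        chosen = rng.choice(len(members), size=k, replace=False)
        for ix in sorted(int(c) for c in chosen):
            zone_of.setdefault(members[ix], "top" if direction == "up" else "bottom")
    top_genes = [g for g, z in zone_of.items() if z == "top"]
    bottom_genes = [g for g, z in zone_of.items() if z == "bottom"]
    if len(top_genes) > decile or len(bottom_genes) > decile:
        raise ValueError(
            f"planted genes ({len(top_genes)} top / {len(bottom_genes)} bottom) "
            f"overflow the decile of {decile} positions"
        )
    order = np.empty(n, dtype=object)
    top_slots = rng.choice(decile, size=len(top_genes), replace=False)
    for g, s in zip(top_genes, top_slots):
        order[int(s)] = g
    bottom_slots = n - decile + rng.choice(decile, size=len(bottom_genes), replace=False)
    for g, s in zip(bottom_genes, bottom_slots):
        order[int(s)] = g
    free_positions = [i for i in range(n) if order[i] is None]
    rest = [g for g in genes if g not in zone_of]
    perm = rng.permutation(len(rest))
    for pos, ix in zip(free_positions, perm):
        order[pos] = rest[int(ix)]
    return tuple(order)


def make_synonym_collisions(
    records: list,
    synonyms: SynonymTable,
    fraction: float,
    seed: Optional[int] = 0,
) -> list:
    """Rewrite a fraction of side-effect drug labels to brand-name aliases.

    Stress-tests the name-normalization step: the returned records refer to
    the same canonical drugs but under brand names, which the synonym table
    must resolve for the merge to recover them.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    lookup = synonyms.lookup_map()
    labels = sorted({r.compound_id for r in records})
    rng = np.random.default_rng(seed)
    n_alias = int(round(fraction * len(labels)))
    chosen = {labels[int(i)] for i in rng.choice(len(labels), size=n_alias, replace=False)}
    alias: dict = {}
    for label in chosen:
        cids = lookup.get(label.strip().lower())
        if not cids or len(cids) > 1:
            continue
        (cid,) = cids
        brands = sorted(synonyms.brands(cid))
        if brands:
            alias[label] = brands[0]
    out = []
    for r in records:
        name = alias.get(r.compound_id, r.compound_id)
        out.append(SideEffectRecord(name, r.umls_cui, r.effect_name,
                                    r.freq_description, r.freq_score))
    return out
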