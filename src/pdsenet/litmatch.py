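"""Literature co-occurrence harness for evaluating process - side-effect links.

Given noun phrases pre-extracted from abstracts that mention a side effect,
each phrase is matched against GO term names by normalized edit-distance
similarity (1 - distance / max length after lowercasing); a phrase counts for
a term when the similarity reaches a threshold (0.55 by default).  Per-term
match counts form a literature ranking, and the pipeline's predicted terms are
scored by how many fall inside the top 10%...50% of that ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import edlib

__all__ = [
    "LiteratureScore",
    "OverlapReport",
    "string_similarity",
    "match_terms",
    "topn_overlap",
]

DEFAULT_FRACTIONS: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class LiteratureScore:
    go_id: str
    effect_name: str
    co_count: int
    score: float

    def __post_init__(self) -> None:
        if self.co_count < 0:
            raise ValueError("co_count must be non-negative")


@dataclass(frozen=True)
class OverlapReport:
    """Per-fraction overlap between predicted terms and the literature ranking."""

    effect_name: str
    fractions: tuple  # of (top_fraction, n_candidate_terms, n_overlap)


def string_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity in [0, 1] after lowercasing.

    1.0 iff the strings are equal after normalization (two empty strings are
    defined as identical); symmetric in its arguments.
    """
    na, nb = a.strip().lower(), b.strip().lower()
    longest = max(len(na), len(nb))
    if longest == 0:
        return 1.0
    dist = edlib.align(na, nb, task="distance")["editDistance"]
    return 1.0 - dist / longest


def match_terms(
    phrases: Sequence[str],
    terms: Sequence,
    threshold: float = 0.55,
    effect_name: str = "",
    normalize: bool = False,
) -> list:
    """Count phrase matches per GO term at a similarity threshold.

    ``terms`` are gene sets (their ``term_name`` is matched).  With
    ``normalize=True`` scores are match counts divided by the total match
    count for the effect; otherwise raw counts.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    counts = []
    for t in terms:
        c = sum(1 for p in phrases if string_similarity(p, t.term_name) >= threshold)
        counts.append((t.go_id, c))
    total = sum(c for _, c in counts)
    scores = []
    for go_id, c in counts:
        score = c / total if (normalize and total > 0) else float(c)
        scores.append(LiteratureScore(go_id, effect_name, c, score))
    return scores


def topn_overlap(
    predicted: Iterable[str],
    lit: Sequence[LiteratureScore],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    effect_name: Optional[str] = None,
) -> OverlapReport:
    """How many predicted terms sit inside the top-n% of the literature ranking.

    Terms are ranked by literature score descending with lexical GO-id
    tie-break; the top-f cut keeps ``ceil(f * |lit|)`` terms.
    """
    if not lit:
        raise ValueError("literature ranking is empty")
    predicted_set = set(predicted)
    ranked = sorted(lit, key=lambda s: (-s.score, s.go_id))
    name = effect_name if effect_name is not None else lit[0].effect_name
    rows = []
    for f in fractions:
        cutoff = math.ceil(f * len(ranked))
        top = {s.go_id for s in ranked[:cutoff]}
        rows.append((f, len(predicted_set), len(predicted_set & top)))
    return OverlapReport(name, tuple(rows))
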