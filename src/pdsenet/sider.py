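"""Drug -> side-effect layer: frequency parsing, filtering, name normalization.

Side-effect records follow the SIDER convention: a compound label, a UMLS
concept id (CUI) naming the effect, the effect name, and a free-text frequency
description that is either a percentage ("26%"), a percentage range
("10-20%"), or a qualitative descriptor ("rare", "infrequent",
"postmarketing").  Only relations observed frequently enough are trusted to
build the drug -> side-effect network; the default cutoff keeps frequencies of
at least 20%.

Drug labels in side-effect records and in expression data rarely agree, so a
DrugBank-style synonym table (canonical id, name, name type in
{primary, synonym, brand}) maps every label to a canonical drug.  Matching is
exact after trimming and lowercasing — fuzzy matching of drug names silently
merges distinct compounds and is deliberately not offered.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "DEFAULT_QUALITATIVE_MAP",
    "SideEffectRecord",
    "DrugSideEffectEdge",
    "SynonymTable",
    "AmbiguousNameError",
    "NormalizationResult",
    "parse_frequency",
    "resolve_frequencies",
    "filter_by_frequency",
    "normalize_drug_names",
]

logger = logging.getLogger(__name__)

#: Qualitative frequency descriptors and their numeric scores.
DEFAULT_QUALITATIVE_MAP: Mapping[str, float] = {
    "postmarketing": 0.001,
    "rare": 0.001,
    "infrequent": 0.01,
}

_CUI_RE = re.compile(r"^C\d+$")
_PCT_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*%$")
_PCT_RANGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*[-–—]\s*(\d+(?:\.\d+)?)\s*%$")


@dataclass(frozen=True)
class SideEffectRecord:
    """One SIDER-style row.  ``compound_id`` is the drug label as the side-effect
    source spells it (to be normalized against the synonym table)."""

    compound_id: str
    umls_cui: str
    effect_name: str
    freq_description: Optional[str] = None
    freq_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not _CUI_RE.match(self.umls_cui):
            raise ValueError(f"invalid UMLS CUI {self.umls_cui!r} (expected C followed by digits)")
        if self.freq_score is not None and not 0.0 <= self.freq_score <= 1.0:
            raise ValueError(f"frequency score {self.freq_score} outside [0, 1]")


@dataclass(frozen=True)
class DrugSideEffectEdge:
    """Frequency-filtered drug -> side-effect relation under a canonical drug name."""

    drug_id: str
    drug_name: str
    umls_cui: str
    effect_name: str
    freq_score: float


class AmbiguousNameError(ValueError):
    """A drug label maps to two or more canonical drugs."""


def _norm(name: str) -> str:
    return name.strip().lower()


@dataclass
class SynonymTable:
    """Canonical drug id -> primary name, synonyms, and brand names."""

    entries: dict = field(default_factory=dict)  # canonical_id -> (primary, set, set)

    def add(self, canonical_id: str, name: str, name_type: str) -> None:
        primary, synonyms, brands = self.entries.setdefault(canonical_id, [None, set(), set()])
        if name_type == "primary":
            self.entries[canonical_id][0] = name
        elif name_type == "synonym":
            synonyms.add(name)
        elif name_type == "brand":
            brands.add(name)
        else:
            raise ValueError(f"unknown name type {name_type!r}")

    def primary_name(self, canonical_id: str) -> str:
        primary = self.entries[canonical_id][0]
        if primary is None:
            raise ValueError(f"drug {canonical_id!r} has no primary name")
        return primary

    def brands(self, canonical_id: str) -> frozenset:
        return frozenset(self.entries[canonical_id][2])

    def lookup_map(self) -> dict:
        """Normalized label -> set of canonical ids claiming it."""
        table: dict = {}
        for cid, (primary, synonyms, brands) in self.entries.items():
            names = set(synonyms) | set(brands)
            if primary is not None:
                names.add(primary)
            for name in names:
                table.setdefault(_norm(name), set()).add(cid)
        return table

    def rows(self):
        for cid in sorted(self.entries):
            primary, synonyms, brands = self.entries[cid]
            if primary is not None:
                yield cid, primary, "primary"
            for name in sorted(synonyms):
                yield cid, name, "synonym"
            for name in sorted(brands):
                yield cid, name, "brand"


def parse_frequency(
    description: Optional[str],
    qualitative_map: Optional[Mapping[str, float]] = None,
) -> Optional[float]:
    """Resolve a frequency description to a score in [0, 1], or None.

    "X%" maps to X/100, "X-Y%" to the midpoint, qualitative descriptors go
    through the (case-insensitive) map; anything else yields None.
    """
    if description is None:
        return None
    text = description.strip()
    if not text:
        return None
    qmap = DEFAULT_QUALITATIVE_MAP if qualitative_map is None else qualitative_map
    qual = {k.lower(): v for k, v in qmap.items()}.get(text.lower())
    if qual is not None:
        return qual
    m = _PCT_RANGE_RE.match(text)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo + hi) / 2.0 / 100.0
    m = _PCT_RE.match(text)
    if m:
        return float(m.group(1)) / 100.0
    logger.info("unparseable frequency description %r; treated as missing", description)
    return None


def resolve_frequencies(
    records: Iterable[SideEffectRecord],
    qualitative_map: Optional[Mapping[str, float]] = None,
) -> list:
    """Fill missing ``freq_score`` fields from the description column."""
    out = []
    for r in records:
        if r.freq_score is not None:
            out.append(r)
            continue
        score = parse_frequency(r.freq_description, qualitative_map)
        out.append(
            SideEffectRecord(r.compound_id, r.umls_cui, r.effect_name, r.freq_description, score)
        )
    return out


def filter_by_frequency(
    records: Iterable[SideEffectRecord],
    min_freq: float = 0.2,
    inclusive: bool = True,
) -> list:
    """Keep records whose frequency score clears the cutoff; drop missing ones."""
    if not 0.0 <= min_freq <= 1.0:
        raise ValueError(f"min_freq {min_freq} outside [0, 1]")
    kept = []
    for r in records:
        if r.freq_score is None:
            continue
        if r.freq_score >= min_freq if inclusive else r.freq_score > min_freq:
            kept.append(r)
    return kept


@dataclass
class NormalizationResult:
    edges: list
    n_unmatched: int
    unmatched_names: list


def normalize_drug_names(
    records: Iterable[SideEffectRecord],
    synonyms: SynonymTable,
) -> NormalizationResult:
    """Map record drug labels to canonical drugs via the synonym table.

    Matching is case-insensitive after trimming.  Unmatched records are
    dropped and counted; a label claimed by two or more canonical drugs
    raises :class:`AmbiguousNameError` naming the collision.
    """
    lookup = synonyms.lookup_map()
    edges: list = []
    unmatched: list = []
    for r in records:
        key = _norm(r.compound_id)
        cids = lookup.get(key)
        if not cids:
            unmatched.append(r.compound_id)
            continue
        if len(cids) > 1:
            raise AmbiguousNameError(
                f"label {r.compound_id!r} maps to multiple drugs: {sorted(cids)}"
            )
        (cid,) = cids
        score = r.freq_score if r.freq_score is not None else float("nan")
        edges.append(
            DrugSideEffectEdge(cid, synonyms.primary_name(cid), r.umls_cui, r.effect_name, score)
        )
    if unmatched:
        logger.info("%d side-effect record(s) dropped: label not in synonym table", len(unmatched))
    return NormalizationResult(edges, len(unmatched), unmatched)
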