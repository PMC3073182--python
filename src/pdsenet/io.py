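"""Readers and writers for every dialect the pipeline touches.

All intermediate artifacts are flat, headered TSV so they can be inspected
and diffed; writers emit deterministic row order for identical inputs.
Dialects:

* rank matrix — rows = genes/probes, columns = instance ids, cells = ranks
  1..N per column (a permutation); a sidecar metadata TSV maps instance id to
  drug name;
* GMT — standard tab-separated gene sets (name, description, members...);
* side-effect records — the 5-column SIDER-style table (compound label, UMLS
  CUI, effect name, frequency description, frequency score);
* synonym table — (canonical_id, name, name_type in {primary,synonym,brand});
* drug - side-effect edges — canonical id, drug name, CUI, effect name (plus
  the frequency score);
* associations — CUI, GO id, CD, TD (plus score and significance), the
  up-regulated dialect ``additional2`` and the down-regulated ``additional3``;
* GraphML for the tripartite network.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .abc import ABCNetwork, CoThresholdTable, ProcessEffectAssociation, to_graph
from .enrichment import DrugProcessEdge, GeneSet, RankMatrix, RankedInstance
from .sider import DrugSideEffectEdge, SideEffectRecord, SynonymTable

__all__ = [
    "FormatError",
    "read_rank_matrix",
    "write_rank_matrix",
    "read_gmt",
    "write_gmt",
    "read_side_effects",
    "write_side_effects",
    "read_synonyms",
    "write_synonyms",
    "read_dp_edges",
    "write_dp_edges",
    "read_dse_edges",
    "write_dse_edges",
    "read_association_file",
    "write_association_file",
    "write_thresholds",
    "write_groundtruth",
    "write_graphml",
    "write_scenario",
]

logger = logging.getLogger(__name__)

ASSOCIATION_DIALECTS = {"additional2": "up", "additional3": "down"}


class FormatError(ValueError):
    """An input file violates its dialect."""


def _open_writer(path):
    return open(path, "w", newline="")


# --- rank matrix ---------------------------------------------------------


def write_rank_matrix(matrix: RankMatrix, path, metadata_path) -> None:
    genes = sorted(matrix.universe)
    data = {}
    for inst in matrix.instances:
        rank_of = {g: r + 1 for r, g in enumerate(inst.ordered_genes)}
        data[inst.instance_id] = [rank_of[g] for g in genes]
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    df.to_csv(path, sep="\t")
    with _open_writer(metadata_path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["instance_id", "drug_name"])
        for inst in matrix.instances:
            w.writerow([inst.instance_id, inst.drug_name])


def read_rank_matrix(path, metadata_path) -> RankMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    n = len(df)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"instance_id", "drug_name"} <= set(meta.columns):
        raise FormatError(f"{metadata_path}: expected columns instance_id, drug_name")
    drug_of = dict(zip(meta["instance_id"].astype(str), meta["drug_name"].astype(str)))
    instances = []
    for _, row in meta.iterrows():
        col = str(row["instance_id"])
        if col not in df.columns:
            raise FormatError(f"{path}: metadata instance {col!r} missing from matrix")
        ranks = df[col]
        counts = ranks.value_counts()
        dup = counts[counts > 1]
        if not dup.empty:
            raise FormatError(f"{path}: column {col!r} repeats rank {int(dup.index[0])}")
        if sorted(ranks) != list(range(1, n + 1)):
            raise FormatError(f"{path}: column {col!r} is not a permutation of 1..{n}")
        ordered = tuple(ranks.sort_values().index.astype(str))
        instances.append(RankedInstance(col, drug_of[col], ordered))
    return RankMatrix(instances, frozenset(df.index.astype(str)))


# --- GMT gene sets -------------------------------------------------------


def read_gmt(path) -> list:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3")
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if len(set(members)) != len(members):
                logger.warning("%s:%d: duplicate genes in %s deduplicated", path, lineno, name)
            sets.append(GeneSet(name, desc, frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with _open_writer(path) as fh:
        for gs in sets:
            fh.write("\t".join([gs.go_id, gs.term_name, *sorted(gs.genes)]) + "\n")


# --- side-effect records and synonyms ------------------------------------


def write_side_effects(records: Sequence[SideEffectRecord], path) -> None:
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["compound_id", "umls_cui", "effect_name", "freq_description", "freq_score"])
        for r in records:
            w.writerow([
                r.compound_id, r.umls_cui, r.effect_name,
                r.freq_description or "",
                "" if r.freq_score is None else repr(r.freq_score),
            ])


def read_side_effects(path) -> list:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            score = row.get("freq_score") or None
            records.append(
                SideEffectRecord(
                    row["compound_id"], row["umls_cui"], row["effect_name"],
                    row.get("freq_description") or None,
                    None if score is None else float(score),
                )
            )
    return records


def write_synonyms(table: SynonymTable, path) -> None:
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["canonical_id", "name", "name_type"])
        for row in table.rows():
            w.writerow(row)


def read_synonyms(path) -> SynonymTable:
    table = SynonymTable()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            table.add(row["canonical_id"], row["name"], row["name_type"])
    return table


# --- edge layers ---------------------------------------------------------


def write_dp_edges(edges: Sequence[DrugProcessEdge], path) -> None:
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["drug_name", "go_id", "direction", "t_score", "instance_id"])
        for e in sorted(edges, key=lambda e: (e.drug_name, e.go_id, e.direction, e.instance_id)):
            w.writerow([e.drug_name, e.go_id, e.direction, repr(e.t), e.instance_id])


def read_dp_edges(path) -> list:
    edges = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            edges.append(DrugProcessEdge(row["drug_name"], row["go_id"], row["direction"],
                                         float(row["t_score"]), row["instance_id"]))
    return edges


def write_dse_edges(edges: Sequence[DrugSideEffectEdge], path) -> None:
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["drug_id", "drug_name", "umls_cui", "effect_name", "freq_score"])
        for e in sorted(edges, key=lambda e: (e.drug_id, e.umls_cui)):
            w.writerow([e.drug_id, e.drug_name, e.umls_cui, e.effect_name, repr(e.freq_score)])


def read_dse_edges(path) -> list:
    edges = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            edges.append(DrugSideEffectEdge(row["drug_id"], row["drug_name"], row["umls_cui"],
                                            row["effect_name"], float(row["freq_score"])))
    return edges


# --- associations and thresholds -----------------------------------------


def write_association_file(
    assocs: Sequence[ProcessEffectAssociation], path, dialect: str
) -> None:
    """Write associations in the up- (``additional2``) or down-regulated
    (``additional3``) dialect: CUI, GO id, CD, TD, then score and significance."""
    if dialect not in ASSOCIATION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    direction = ASSOCIATION_DIALECTS[dialect]
    for a in assocs:
        if a.direction != direction:
            raise ValueError(
                f"dialect {dialect!r} holds {direction}-regulated processes; "
                f"association ({a.umls_cui}, {a.go_id}) is {a.direction!r}"
            )
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["umls_cui", "go_id", "cd", "td", "score", "significant"])
        for a in sorted(assocs, key=lambda a: (a.umls_cui, a.go_id)):
            w.writerow([a.umls_cui, a.go_id, a.cd, a.td, f"{a.score:.2f}", int(a.significant)])


def read_association_file(path, dialect: str) -> list:
    if dialect not in ASSOCIATION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    direction = ASSOCIATION_DIALECTS[dialect]
    assocs = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cd, td = int(row["cd"]), int(row["td"])
            assocs.append(
                ProcessEffectAssociation(row["umls_cui"], row["go_id"], direction, cd, td,
                                         cd / td, bool(int(row["significant"])))
            )
    return assocs


def write_thresholds(table: CoThresholdTable, path) -> None:
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["td", "min_significant_cd", "alpha", "n_perm", "direction"])
        for td in sorted(table.thresholds):
            thr = table.thresholds[td]
            w.writerow([td, "unattainable" if thr is None else thr,
                        table.alpha, table.n_perm, table.direction or ""])


def write_groundtruth(truth, path) -> None:
    """Planted structure as (layer, source_id, target_id, direction) rows."""
    with _open_writer(path) as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["layer", "source_id", "target_id", "direction"])
        for drug, go, direction in sorted(truth.drug_process_plants):
            w.writerow(["drug_process", drug, go, direction])
        for go, cui, direction in sorted(truth.process_effect_links):
            w.writerow(["process_effect", go, cui, direction])
        for (drug, cui) in sorted(truth.drug_effect_links):
            w.writerow(["drug_effect", drug, cui, ""])


def write_graphml(network: ABCNetwork, path, assocs=None) -> None:
    nx.write_graphml(to_graph(network, assocs), path)


def write_scenario(scenario, outdir) -> dict:
    """Write all four synthetic inputs plus the ground truth; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rank_matrix": outdir / "rank_matrix.tsv",
        "metadata": outdir / "instances.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "side_effects": outdir / "side_effects.tsv",
        "synonyms": outdir / "synonyms.tsv",
        "groundtruth": outdir / "groundtruth.tsv",
    }
    write_rank_matrix(scenario.rank_matrix, paths["rank_matrix"], paths["metadata"])
    write_gmt(scenario.gene_sets, paths["gene_sets"])
    write_side_effects(scenario.side_effects, paths["side_effects"])
    write_synonyms(scenario.synonyms, paths["synonyms"])
    write_groundtruth(scenario.truth, paths["groundtruth"])
    return paths
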