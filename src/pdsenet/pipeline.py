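"""End-to-end orchestration: enrichment -> side-effect layer -> ABC scoring.

`run_from_objects` drives the whole analysis on in-memory inputs and returns
every intermediate product; `run_pipeline` wraps it with file I/O, writing
all outputs, a machine-readable run summary, and a log into a run directory.
Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .abc import apply_thresholds, co_occurrence, merge_networks, permutation_thresholds
from .config import PipelineConfig
from .enrichment import compute_es_matrix, filter_edges, median_mad_tscores
from .sider import filter_by_frequency, normalize_drug_names, resolve_frequencies

__all__ = ["PipelineResult", "StageError", "run_from_objects", "run_pipeline"]

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    dp_edges: list
    dse_edges: list
    network: object
    associations: dict  # direction -> list of ProcessEffectAssociation
    thresholds: dict  # direction -> CoThresholdTable
    summary: dict = field(default_factory=dict)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_from_objects(config: PipelineConfig, matrix, gene_sets, records, synonyms) -> PipelineResult:
    """Run enrichment, side-effect filtering, merge, and co-occurrence scoring."""
    summary: dict = {
        "n_instances": matrix.n_instances,
        "n_genes": matrix.n_genes,
        "n_gene_sets": len(gene_sets),
        "n_side_effect_records": len(records),
    }

    with _stage("enrichment"):
        tscores = []
        for direction in DIRECTIONS:
            es = compute_es_matrix(matrix, gene_sets, direction)
            ts, stats = median_mad_tscores(es)
            tscores.extend(ts)
            summary[f"n_es_{direction}"] = len(es)
            summary[f"n_degenerate_rows_{direction}"] = sum(s.degenerate for s in stats)
        dp_edges = filter_edges(
            tscores, matrix, gene_sets,
            t_threshold=config.t_threshold,
            max_set_genes=config.max_set_genes,
            aggregation=config.aggregation,
        )
        summary["n_dp_edges"] = len(dp_edges)

    with _stage("side_effects"):
        resolved = resolve_frequencies(records)
        filtered = filter_by_frequency(resolved, config.min_freq, config.inclusive_freq)
        norm = normalize_drug_names(filtered, synonyms)
        dse_edges = norm.edges
        summary["n_frequency_filtered"] = len(filtered)
        summary["n_dse_edges"] = len(dse_edges)
        summary["n_unmatched_names"] = norm.n_unmatched

    with _stage("merge"):
        network = merge_networks(dp_edges, dse_edges)
        summary["bridge"] = network.summary()

    associations: dict = {}
    thresholds: dict = {}
    with _stage("co_occurrence"):
        seeds = np.random.SeedSequence(config.seed).spawn(len(DIRECTIONS))
        for direction, seed in zip(DIRECTIONS, seeds):
            assocs = co_occurrence(network, config.min_drugs, direction)
            table = permutation_thresholds(
                network, n_perm=config.n_perm, alpha=config.alpha, seed=seed,
                direction=direction, min_drugs=config.min_drugs, plus_one=config.plus_one,
            )
            associations[direction] = apply_thresholds(assocs, table)
            thresholds[direction] = table
            summary[f"n_associations_{direction}"] = len(assocs)
            summary[f"n_significant_{direction}"] = sum(a.significant for a in associations[direction])

    summary["n_associations"] = sum(summary[f"n_associations_{d}"] for d in DIRECTIONS)
    summary["n_significant"] = sum(summary[f"n_significant_{d}"] for d in DIRECTIONS)
    return PipelineResult(dp_edges, dse_edges, network, associations, thresholds, summary)


def run_pipeline(
    config: PipelineConfig,
    rank_matrix_path,
    metadata_path,
    gmt_path,
    side_effects_path,
    synonyms_path,
    outdir,
) -> dict:
    """File-based end-to-end run; returns the run summary (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pdsenet")
    root.addHandler(handler)
    try:
        with _stage("read_inputs"):
            matrix = pio.read_rank_matrix(rank_matrix_path, metadata_path)
            gene_sets = pio.read_gmt(gmt_path)
            records = pio.read_side_effects(side_effects_path)
            synonyms = pio.read_synonyms(synonyms_path)

        result = run_from_objects(config, matrix, gene_sets, records, synonyms)

        with _stage("write_outputs"):
            pio.write_dp_edges(result.dp_edges, outdir / "dp_edges.tsv")
            pio.write_dse_edges(result.dse_edges, outdir / "dse_edges.tsv")
            for direction, dialect in (("up", "additional2"), ("down", "additional3")):
                pio.write_association_file(
                    result.associations[direction],
                    outdir / f"associations_{direction}.tsv", dialect,
                )
                pio.write_thresholds(result.thresholds[direction],
                                     outdir / f"thresholds_{direction}.tsv")
            pio.write_graphml(
                result.network, outdir / "network.graphml",
                [a for d in DIRECTIONS for a in result.associations[d]],
            )
            config.to_yaml(outdir / "config.yaml")
            with open(outdir / "summary.json", "w") as fh:
                json.dump(result.summary, fh, indent=2, sort_keys=True)
        return result.summary
    finally:
        root.removeHandler(handler)
        handler.close()
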