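"""End-to-end orchestration: load → graph → search → score → evaluate.

The full run mirrors the method's four stages: collect per-cell scored
assemblies, build the fragment graph, enumerate merging-score candidates,
then apply the two-stage random-forest scoring. Training uses candidates
on the training chromosomes (default 1–9) labeled against ground truth;
the held-out chromosomes measure generalization. All randomness flows
from the single seed in :class:`RunConfig`, and every stage logs its
counts into a JSON manifest so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .evaluation import evaluate_dataset
from .features import cell_feature_matrix, general_feature_matrix
from .fragment_graph import build_graph, connected_components
from .gtf_io import (
    CellAssembly,
    IntronChain,
    ScoredAssembly,
    read_cell_gtf,
    write_candidate_gtf,
    write_scored_gtf,
)
from .models import (
    DEFAULT_TRAIN_CHROMS,
    ModelBundle,
    filter_general,
    label_general,
    label_specific,
    score_cells,
    split_by_chromosome,
    train_general,
    train_specific,
)
from .path_search import (
    CandidatePath,
    FragmentIndex,
    SearchParams,
    search_all,
    write_candidate_tsv,
)

__all__ = ["RunConfig", "AssembleResult", "PipelineResult", "run_assemble",
           "run_full", "load_assemblies"]

logger = logging.getLogger("beaver")


@dataclass
class RunConfig:
    """Reproducible run settings; echoed verbatim into the manifest."""

    input_dir: str | None = None
    score_attribute: str = "cov"
    pn: int = 15
    pc: int = 100
    theta: float = 0.2
    tau: float = 0.5
    train_chroms: tuple[str, ...] = tuple(sorted(DEFAULT_TRAIN_CHROMS))
    seed: int = 42
    output_dir: str | None = None

    @property
    def search_params(self) -> SearchParams:
        return SearchParams(pn=self.pn, pc=self.pc)


def load_assemblies(
    input_dir: str | os.PathLike, score_attribute: str = "cov"
) -> list[CellAssembly]:
    """One GTF per cell; file name (sans extension) is the cell id."""
    paths = sorted(
        p for p in os.listdir(input_dir) if p.endswith(".gtf")
    )
    if not paths:
        raise FileNotFoundError(f"no .gtf files in {input_dir}")
    return [
        read_cell_gtf(
            os.path.join(input_dir, p), score_attribute=score_attribute
        )
        for p in paths
    ]


@dataclass
class AssembleResult:
    candidates: list[CandidatePath]
    index: FragmentIndex
    counts: dict[str, int] = field(default_factory=dict)


def run_assemble(
    assemblies: Sequence[CellAssembly], config: RunConfig
) -> AssembleResult:
    """Stages one to three: graph construction and candidate search."""
    if not assemblies:
        raise ValueError("no input assemblies")
    index = FragmentIndex(assemblies)
    graph = build_graph(assemblies)
    components = connected_components(graph)
    candidates = search_all(components, config.search_params, index)
    counts = {
        "cells": len(assemblies),
        "fragments_loaded": sum(len(a.fragments) for a in assemblies),
        "vertices": len(graph.vertices),
        "edges": len(graph.edges),
        "components": len(components),
        "candidates": len(candidates),
    }
    logger.info("assembly stage: %s", counts)
    return AssembleResult(candidates=candidates, index=index, counts=counts)


@dataclass
class PipelineResult:
    config: RunConfig
    candidates: list[CandidatePath]
    filtered: list[CandidatePath]
    bundle: ModelBundle
    #: scored (candidate_id, cell, probability) for every eligible pair
    pair_scores: pd.DataFrame
    #: per-cell output assemblies at threshold tau
    scored: dict[str, ScoredAssembly]
    counts: dict[str, int]
    index: FragmentIndex

    def predictions_by_cell(
        self, chroms: set[str] | None = None
    ) -> dict[str, list[tuple[IntronChain, float]]]:
        """Scored chains per cell (every eligible pair, ignoring tau),
        optionally restricted to a chromosome set."""
        by_id = {p.id: p for p in self.filtered}
        out: dict[str, list[tuple[IntronChain, float]]] = {
            cell: [] for cell in self.index.cells
        }
        for cand_id, cell, prob in self.pair_scores.itertuples(index=False):
            chain = by_id[cand_id].chain
            if chroms is not None and _models.normalize_chrom(chain.chrom) not in chroms:
                continue
            out[cell].append((chain, float(prob)))
        return out


def run_full(
    assemblies: Sequence[CellAssembly],
    config: RunConfig,
    per_cell_truth: Mapping[str, set[IntronChain]] | None = None,
    reference_chains: set[IntronChain] | None = None,
    bundle: ModelBundle | None = None,
) -> PipelineResult:
    """Train (or reuse) the two models and produce per-cell assemblies.

    Training mode needs ground truth: per-cell truths when available,
    otherwise a reference annotation stands in for both labeling stages
    (each cell is then labeled against the same unified chain set).
    Inference mode takes a fitted :class:`ModelBundle` instead.
    """
    if bundle is None and per_cell_truth is None and reference_chains is None:
        raise ValueError("need ground truth (training) or a model bundle")

    assemble = run_assemble(assemblies, config)
    candidates, index = assemble.candidates, assemble.index
    counts = dict(assemble.counts)
    train_set = frozenset(_models.normalize_chrom(c) for c in config.train_chroms)

    if per_cell_truth is not None:
        union_truth: set[IntronChain] = set()
        for chains in per_cell_truth.values():
            union_truth |= chains
    else:
        union_truth = set(reference_chains or set())

    general_X = general_feature_matrix(candidates, index)

    if bundle is None:
        chroms = [p.chrom for p in candidates]
        train_mask, _ = split_by_chromosome(chroms, train_set)
        labels_g = label_general(candidates, union_truth)
        general = train_general(
            general_X[train_mask], labels_g[train_mask], seed=config.seed
        )
    else:
        general = bundle.general

    scores_g = _models._positive_proba(general, general_X.to_numpy())
    filtered, kept_scores = filter_general(candidates, scores_g, config.theta)
    counts["candidates_after_filter"] = len(filtered)
    logger.info(
        "general filter kept %d / %d candidates at theta=%.2f",
        len(filtered), len(candidates), config.theta,
    )

    pair_X = cell_feature_matrix(filtered, index)
    by_id = {p.id: p for p in filtered}
    pairs = [(by_id[cid], cell) for cid, cell in pair_X.index]
    counts["eligible_pairs"] = len(pairs)

    if bundle is None:
        if per_cell_truth is not None:
            labels_s = label_specific(pairs, per_cell_truth)
        else:
            labels_s = np.array(
                [1 if p.chain in union_truth else 0 for p, _ in pairs],
                dtype=int,
            )
        pair_chroms = [p.chrom for p, _ in pairs]
        train_mask_s, _ = split_by_chromosome(pair_chroms, train_set)
        specific = train_specific(
            pair_X[train_mask_s], labels_s[train_mask_s], seed=config.seed
        )
        bundle = ModelBundle(
            general=general,
            specific=specific,
            theta=config.theta,
            seed=config.seed,
            train_chroms=tuple(sorted(train_set)),
        )
    else:
        specific = bundle.specific

    scored, pair_scores = score_cells(
        filtered, index, specific, tau=config.tau, pair_features=pair_X
    )
    counts["output_transcripts"] = sum(
        len(a.transcripts) for a in scored.values()
    )
    logger.info("pipeline counts: %s", counts)

    result = PipelineResult(
        config=config,
        candidates=candidates,
        filtered=filtered,
        bundle=bundle,
        pair_scores=pair_scores,
        scored=scored,
        counts=counts,
        index=index,
    )
    if config.output_dir:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    outdir = result.config.output_dir
    os.makedirs(outdir, exist_ok=True)
    write_candidate_gtf(
        result.filtered, os.path.join(outdir, "candidates.gtf")
    )
    write_candidate_tsv(
        result.filtered, os.path.join(outdir, "candidates.tsv")
    )
    for cell, assembly in sorted(result.scored.items()):
        write_scored_gtf(assembly, os.path.join(outdir, f"{cell}.scored.gtf"))
    result.bundle.save(os.path.join(outdir, "model.bundle"))
    manifest = {"config": asdict(result.config), "counts": result.counts}
    with open(os.path.join(outdir, "manifest.json"), "w") as out:
        json.dump(manifest, out, indent=2)


def evaluate_pipeline(
    result: PipelineResult,
    per_cell_truth: Mapping[str, set[IntronChain]],
    chroms: set[str] | None = None,
):
    """Per-cell evaluation of the scored output, optionally restricted to
    a chromosome set (e.g. the held-out test chromosomes)."""
    predictions = result.predictions_by_cell(chroms)
    truth = {
        cell: {
            c
            for c in chains
            if chroms is None or _models.normalize_chrom(c.chrom) in chroms
        }
        for cell, chains in per_cell_truth.items()
    }
    return evaluate_dataset(predictions, truth)
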