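"""Two-stage random-forest scoring of candidate transcripts.

Stage one (the *general* model) scores each candidate full-length
transcript independently of cells, using the 30 general features;
candidates scoring below a threshold θ (default 0.2) are discarded,
which both removes obvious false positives and balances the classes seen
by stage two. Stage two (the *cell-specific* model) scores each surviving
(candidate, cell) pair with all 51 features, estimating the probability
that the candidate is correctly assembled *and* expressed in that cell.

Both models are random forests with n_estimators=100 and max_depth=12.
Labels come from intron-chain matching against ground truth: the general
label is 1 when the candidate's chain occurs in the union of all cells'
truths (or a reference annotation), the specific label is 1 only when it
occurs in that particular cell's truth. Training uses chromosomes 1–9
exclusively; everything else is held out.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import (
    CELL_NAMES,
    GENERAL_NAMES,
    SCHEMA_VERSION,
    cell_feature_matrix,
)
from .gtf_io import IntronChain, ScoredAssembly, ScoredTranscript
from .path_search import CandidatePath, FragmentIndex

__all__ = [
    "DEFAULT_TRAIN_CHROMS",
    "ModelBundle",
    "label_general",
    "label_specific",
    "split_by_chromosome",
    "train_general",
    "filter_general",
    "train_specific",
    "score_cells",
]

DEFAULT_TRAIN_CHROMS = frozenset(str(i) for i in range(1, 10))

_RF_PARAMS = dict(n_estimators=100, max_depth=12)


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def label_general(
    candidates: Sequence[CandidatePath],
    truth_chains: set[IntronChain],
) -> np.ndarray:
    """1 iff the candidate's chain matches the unified ground truth."""
    if not truth_chains:
        warnings.warn("empty ground truth: all general labels are 0")
    return np.array(
        [1 if p.chain in truth_chains else 0 for p in candidates], dtype=int
    )


def label_specific(
    pairs: Sequence[tuple[CandidatePath, str]],
    per_cell_truth: Mapping[str, set[IntronChain]],
) -> np.ndarray:
    """1 iff the candidate's chain occurs in that cell's own truth."""
    labels = []
    missing: set[str] = set()
    for path, cell in pairs:
        truth = per_cell_truth.get(cell)
        if truth is None:
            missing.add(cell)
            labels.append(0)
        else:
            labels.append(1 if path.chain in truth else 0)
    if missing:
        warnings.warn(f"cells absent from truth, labeled 0: {sorted(missing)}")
    return np.array(labels, dtype=int)


def split_by_chromosome(
    chroms: Sequence[str],
    train_chroms: frozenset[str] | set[str] = DEFAULT_TRAIN_CHROMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (train_mask, test_mask): a disjoint, exhaustive partition
    of example indices by chromosome ('chr' prefixes accepted)."""
    normalized = {normalize_chrom(c) for c in train_chroms}
    train = np.array(
        [normalize_chrom(c) in normalized for c in chroms], dtype=bool
    )
    if len(train) and not train.any():
        warnings.warn("no examples on training chromosomes")
    return train, ~train


def _fit_forest(X: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            "training set contains a single class; cannot fit a classifier"
        )
    forest = RandomForestClassifier(random_state=seed, **_RF_PARAMS)
    forest.fit(X, y)
    return forest


def _positive_proba(model: RandomForestClassifier, X) -> np.ndarray:
    pos = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(X)[:, pos]


def train_general(
    features: pd.DataFrame, labels: np.ndarray, seed: int = 42
) -> RandomForestClassifier:
    """Fit the candidate-level forest on the 30 general features."""
    if list(features.columns) != GENERAL_NAMES:
        raise ValueError("feature table does not match the general schema")
    return _fit_forest(features.to_numpy(), labels, seed)


def filter_general(
    candidates: Sequence[CandidatePath],
    scores: np.ndarray,
    theta: float = 0.2,
) -> tuple[list[CandidatePath], np.ndarray]:
    """Keep candidates with general score >= θ (boundary kept)."""
    keep = scores >= theta
    return (
        [p for p, k in zip(candidates, keep) if k],
        scores[keep],
    )


def train_specific(
    features: pd.DataFrame, labels: np.ndarray, seed: int = 42
) -> RandomForestClassifier:
    """Fit the pair-level forest on all 51 features."""
    if list(features.columns) != GENERAL_NAMES + CELL_NAMES:
        raise ValueError("feature table does not match the specific schema")
    return _fit_forest(features.to_numpy(), labels, seed)


def score_cells(
    filtered: Sequence[CandidatePath],
    index: FragmentIndex,
    specific_model: RandomForestClassifier,
    tau: float = 0.5,
    pair_features: pd.DataFrame | None = None,
) -> tuple[dict[str, ScoredAssembly], pd.DataFrame]:
    """Assign Pr(p, c) to every eligible pair and emit per-cell outputs.

    Returns the per-cell assemblies (pairs with Pr >= τ) plus the full
    scored-pair table (candidate_id, cell, probability) regardless of τ,
    which downstream evaluation consumes for score sweeps.
    """
    if pair_features is None:
        pair_features = cell_feature_matrix(filtered, index)
    by_id = {p.id: p for p in filtered}
    assemblies: dict[str, ScoredAssembly] = {
        cell: ScoredAssembly(cell=cell) for cell in index.cells
    }
    if len(pair_features) == 0:
        table = pd.DataFrame(columns=["candidate_id", "cell", "probability"])
        return assemblies, table

    probs = _positive_proba(specific_model, pair_features.to_numpy())
    records = []
    for (cand_id, cell), prob in zip(pair_features.index, probs):
        records.append((cand_id, cell, float(prob)))
        if prob >= tau:
            path = by_id[cand_id]
            assemblies.setdefault(cell, ScoredAssembly(cell=cell))
            assemblies[cell].transcripts.append(
                ScoredTranscript(
                    id=path.id,
                    chrom=path.chrom,
                    strand=path.strand,
                    exons=path.exons,
                    probability=float(prob),
                )
            )
    table = pd.DataFrame(
        records, columns=["candidate_id", "cell", "probability"]
    )
    return assemblies, table


@dataclass
class ModelBundle:
    """Fitted model pair plus the metadata needed to reapply it."""

    general: RandomForestClassifier
    specific: RandomForestClassifier
    theta: float = 0.2
    schema_version: str = SCHEMA_VERSION
    seed: int = 42
    train_chroms: tuple[str, ...] = tuple(sorted(DEFAULT_TRAIN_CHROMS))

    def save(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        joblib.dump({"general": self.general, "specific": self.specific}, path)
        manifest = {
            "schema_version": self.schema_version,
            "theta": self.theta,
            "seed": self.seed,
            "train_chroms": list(self.train_chroms),
            "rf_params": _RF_PARAMS,
        }
        with open(path + ".json", "w") as out:
            json.dump(manifest, out, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ModelBundle":
        path = os.fspath(path)
        models = joblib.load(path)
        with open(path + ".json") as handle:
            manifest = json.load(handle)
        if manifest["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                "model bundle was trained with feature schema "
                f"{manifest['schema_version']}, current is {SCHEMA_VERSION}"
            )
        return cls(
            general=models["general"],
            specific=models["specific"],
            theta=manifest["theta"],
            seed=manifest["seed"],
            train_chroms=tuple(manifest["train_chroms"]),
        )
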