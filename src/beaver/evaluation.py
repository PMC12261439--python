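"""Assembly evaluation by exact intron-chain matching.

A predicted multi-exon transcript *matches* when its full (chromosome,
strand, junction list) equals that of a ground-truth transcript. Two
metrics follow: the number of matching transcripts (proportional to
sensitivity) and precision, the ratio of matching to total assembled
transcripts. Duplicate predictions of one chain credit a single match but
all count in the denominator, mirroring standard transcript-comparison
behavior and penalizing redundancy.

When two methods trade precision against sensitivity, *adjusted precision*
compares them at matched sensitivity: the lower-scoring transcripts of the
more sensitive method are removed, one at a time, until its matching count
first equals the other's; the precision of what remains is the comparison
point — a point on the method's precision–recall curve.

Per-cell evaluation runs in two modes: *cell-specific* (against the cell's
own truth) and *general* (against the union of all cells' truths); the
cell-specific matches of a cell can never exceed its general matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .gtf_io import IntronChain

__all__ = [
    "EvalResult",
    "match_transcripts",
    "adjusted_precision",
    "evaluate_dataset",
]


@dataclass
class EvalResult:
    """Matching outcome for one cell's predicted assembly."""

    cell: str
    n_assembled: int
    n_matching: int
    #: (score, chain, is_match) per prediction, for score sweeps
    flags: list[tuple[float, IntronChain, bool]] = field(default_factory=list)

    @property
    def precision(self) -> float | None:
        if self.n_assembled == 0:
            return None
        return self.n_matching / self.n_assembled


def match_transcripts(
    predictions: Sequence[tuple[IntronChain, float]],
    truth: set[IntronChain],
    cell: str = "",
) -> EvalResult:
    """Match scored predictions against a truth chain set.

    Within a duplicated chain, the highest-scoring occurrence carries the
    match credit; the rest are false positives.
    """
    credited: set[IntronChain] = set()
    flags: list[tuple[float, IntronChain, bool]] = []
    for chain, score in sorted(
        predictions, key=lambda x: (-x[1], x[0].chrom, x[0].junctions)
    ):
        is_match = chain in truth and chain not in credited
        if is_match:
            credited.add(chain)
        flags.append((score, chain, is_match))
    return EvalResult(
        cell=cell,
        n_assembled=len(flags),
        n_matching=len(credited),
        flags=flags,
    )


def adjusted_precision(
    result: EvalResult, target_matches: int
) -> float | None:
    """Precision of *result* after trimming low-scoring predictions until
    its match count first equals *target_matches*.

    Removal is one transcript at a time, lowest score first (ties broken by
    chain for stability). Returns None when the target exceeds the
    achievable match count, or with a zero-size retained set.
    """
    if target_matches > result.n_matching:
        return None
    ordered = sorted(
        result.flags, key=lambda x: (x[0], x[1].chrom, x[1].junctions)
    )
    matches = result.n_matching
    kept = len(ordered)
    i = 0
    while matches > target_matches and i < len(ordered):
        _score, _chain, is_match = ordered[i]
        kept -= 1
        if is_match:
            matches -= 1
        i += 1
    if kept == 0:
        return None
    return matches / kept


def evaluate_dataset(
    predictions: Mapping[str, Sequence[tuple[IntronChain, float]]],
    per_cell_truth: Mapping[str, set[IntronChain]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell metrics in cell-specific and general (union) modes.

    Cells must align by id; predictions for unknown cells are an error.
    Single-exon chains cannot exist in this representation (a chain has at
    least one junction), so no further filtering is needed.
    """
    unmatched = sorted(set(predictions) - set(per_cell_truth))
    if unmatched:
        raise ValueError(f"predictions for cells absent from truth: {unmatched}")
    union: set[IntronChain] = set()
    for chains in per_cell_truth.values():
        union |= chains

    rows = []
    for cell in sorted(per_cell_truth):
        preds = list(predictions.get(cell, ()))
        specific = match_transcripts(preds, set(per_cell_truth[cell]), cell)
        general = match_transcripts(preds, union, cell)
        rows.append(
            {
                "cell": cell,
                "n_assembled": specific.n_assembled,
                "n_matching_specific": specific.n_matching,
                "precision_specific": specific.precision,
                "n_matching_general": general.n_matching,
                "precision_general": general.precision,
            }
        )
    table = pd.DataFrame(rows).set_index("cell")
    summary = {}
    for col in table.columns:
        values = table[col].dropna().astype(float)
        summary[f"median_{col}"] = float(values.median()) if len(values) else float("nan")
        summary[f"mean_{col}"] = float(values.mean()) if len(values) else float("nan")
    return table, summary


def write_eval_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def precision_curve(result: EvalResult) -> pd.DataFrame:
    """Score-threshold sweep: at each distinct score, the retained match
    count and precision (for plotting precision–sensitivity curves)."""
    ordered = sorted(result.flags, key=lambda x: -x[0])
    rows = []
    matches = 0
    for k, (score, _chain, is_match) in enumerate(ordered, start=1):
        matches += bool(is_match)
        rows.append({"score_threshold": score, "n_matching": matches,
                     "precision": matches / k})
    return pd.DataFrame(rows)
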