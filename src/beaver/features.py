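"""Feature engineering for candidate transcripts.

Two feature sets feed the two random-forest models: 30 *general* features
describing how reliable a candidate full-length transcript looks across
the whole cell population, and 21 *cell-specific* features describing how
likely the candidate is expressed in one particular cell. Both draw on
three kinds of evidence:

* junction coverage — per-junction support scores J(j, p) restricted to
  compatible fragments, summarized by min/median/mean/max/std;
* cell support — how many cells, and what fraction of cells, back each
  junction and the candidate as a whole;
* fragment connectivity — whether the candidate keeps an input chain
  intact or was merged from several fragments, and how those fragments
  overlap.

The schema is registry-driven: each feature is a named accessor over a
precomputed per-candidate (or per candidate-cell) context, so the set can
be revised without touching the extraction machinery. Standard deviations
are population standard deviations (well-defined for a single junction).

A (candidate, cell) pair is *eligible* for cell-specific features when at
least one junction of the candidate appears in some fragment of that cell
— mere presence, no compatibility requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .path_search import CandidatePath, FragmentIndex

__all__ = [
    "SCHEMA_VERSION",
    "GENERAL_FEATURES",
    "CELL_FEATURES",
    "general_feature_matrix",
    "cell_feature_matrix",
    "assemble_feature_matrix",
    "eligible_cells",
]

SCHEMA_VERSION = "beaver-features-1"


def _stats5(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, median, mean, max, population std); zeros when empty."""
    if len(values) == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    arr = np.asarray(values, dtype=float)
    return (
        float(arr.min()),
        float(np.median(arr)),
        float(arr.mean()),
        float(arr.max()),
        float(arr.std()),  # ddof=0
    )


@dataclass
class _CandidateContext:
    """Per-candidate aggregates shared by every feature accessor."""

    path: CandidatePath
    n_cells: int
    # per junction position, over compatible fragments of all cells
    junction_scores: tuple[float, ...]
    cell_counts: list[int]  # distinct supporting cells per junction
    fragment_counts: list[int]  # compatible fragments per junction
    supporting_cells: set[str]
    fullchain_cells: set[str]
    # cell -> list of (score, covered positions) of its compatible fragments
    per_cell: dict[str, list[tuple[float, tuple[int, ...]]]]
    # cell -> set of junction positions present in ANY fragment of the cell
    expressed_positions: dict[str, set[int]]
    total_score: float


def _contiguous_full_cover(positions: tuple[int, ...], nj: int) -> bool:
    return len(positions) == nj


def _build_context(
    path: CandidatePath, index: FragmentIndex
) -> _CandidateContext:
    nj = path.n_junctions
    chain = path.chain
    cell_sets: list[set[str]] = [set() for _ in range(nj)]
    frag_counts = [0] * nj
    per_cell: dict[str, list[tuple[float, tuple[int, ...]]]] = {}
    supporting: set[str] = set()
    fullchain: set[str] = set()
    total = 0.0
    for cell, _fid, score, positions in path.support.compatible:
        supporting.add(cell)
        per_cell.setdefault(cell, []).append((score, positions))
        total += score
        for k in positions:
            cell_sets[k].add(cell)
            frag_counts[k] += 1
        if _contiguous_full_cover(positions, nj):
            fullchain.add(cell)

    expressed: dict[str, set[int]] = {}
    for k, junction in enumerate(chain.junctions):
        for frag in index.fragments_with_junction(
            chain.chrom, chain.strand, junction
        ):
            expressed.setdefault(frag.cell, set()).add(k)

    return _CandidateContext(
        path=path,
        n_cells=max(len(index.cells), 1),
        junction_scores=path.support.junction_scores,
        cell_counts=[len(s) for s in cell_sets],
        fragment_counts=frag_counts,
        supporting_cells=supporting,
        fullchain_cells=fullchain,
        per_cell=per_cell,
        expressed_positions=expressed,
        total_score=total,
    )


# ---------------------------------------------------------------------------
# general features (30)

_STAT_NAMES = ("min", "median", "mean", "max", "std")


def _stat_block(prefix: str, getter) -> list[tuple[str, Callable]]:
    return [
        (f"{prefix}_{stat}", lambda c, i=i, g=getter: _stats5(g(c))[i])
        for i, stat in enumerate(_STAT_NAMES)
    ]


def _overlap_stat(ctx: _CandidateContext, fn) -> float:
    ov = ctx.path.overlaps
    return float(fn(ov)) if ov else 0.0


def _longest_fragment_fraction(ctx: _CandidateContext) -> float:
    nj = ctx.path.n_junctions
    best = 0
    for _cell, _fid, _score, positions in ctx.path.support.compatible:
        best = max(best, len(positions))
    return best / nj


GENERAL_FEATURES: list[tuple[str, Callable[[_CandidateContext], float]]] = [
    *_stat_block("junc_score", lambda c: c.junction_scores),
    *_stat_block("junc_cells", lambda c: c.cell_counts),
    *_stat_block("junc_frags", lambda c: c.fragment_counts),
    ("n_junctions", lambda c: float(c.path.n_junctions)),
    ("bottleneck", lambda c: c.path.bottleneck),
    ("merging_score", lambda c: c.path.f_score),
    ("n_supporting_cells", lambda c: float(len(c.supporting_cells))),
    ("prop_supporting_cells", lambda c: len(c.supporting_cells) / c.n_cells),
    ("n_fullchain_cells", lambda c: float(len(c.fullchain_cells))),
    ("prop_fullchain_cells", lambda c: len(c.fullchain_cells) / c.n_cells),
    ("n_vertices", lambda c: float(len(c.path.vertex_indices))),
    (
        "single_fragment",
        lambda c: 1.0 if len(c.path.vertex_indices) == 1 else 0.0,
    ),
    ("longest_fragment_fraction", _longest_fragment_fraction),
    ("overlap_min", lambda c: _overlap_stat(c, min)),
    ("overlap_mean", lambda c: _overlap_stat(c, lambda o: sum(o) / len(o))),
    ("overlap_max", lambda c: _overlap_stat(c, max)),
    ("total_support_score", lambda c: c.total_score),
    ("n_compatible_fragments", lambda c: float(len(c.path.support.compatible))),
]

assert len(GENERAL_FEATURES) == 30


# ---------------------------------------------------------------------------
# cell-specific features (21)


@dataclass
class _CellContext:
    base: _CandidateContext
    cell: str
    cell_scores: list[float]  # per-junction J restricted to this cell
    cell_frag_counts: list[int]
    records: list[tuple[float, tuple[int, ...]]]


def _build_cell_context(ctx: _CandidateContext, cell: str) -> _CellContext:
    nj = ctx.path.n_junctions
    scores = [0.0] * nj
    counts = [0] * nj
    records = ctx.per_cell.get(cell, [])
    for score, positions in records:
        for k in positions:
            scores[k] += score
            counts[k] += 1
    return _CellContext(
        base=ctx,
        cell=cell,
        cell_scores=scores,
        cell_frag_counts=counts,
        records=records,
    )


def _cell_bottleneck(cc: _CellContext) -> float:
    return min(cc.cell_scores)


def _cell_bottleneck_rank(cc: _CellContext) -> float:
    """Fraction of supporting cells whose bottleneck is <= this cell's
    (0 when the cell supports nothing)."""
    if cc.cell not in cc.base.supporting_cells:
        return 0.0
    mine = _cell_bottleneck(cc)
    others = [
        _cell_bottleneck(_build_cell_context(cc.base, other))
        for other in cc.base.supporting_cells
    ]
    return sum(1 for o in others if o <= mine) / len(others)


CELL_FEATURES: list[tuple[str, Callable[[_CellContext], float]]] = [
    *[
        (f"cell_junc_score_{stat}", lambda c, i=i: _stats5(c.cell_scores)[i])
        for i, stat in enumerate(_STAT_NAMES)
    ],
    *[
        (
            f"cell_junc_frags_{stat}",
            lambda c, i=i: _stats5(c.cell_frag_counts)[i],
        )
        for i, stat in enumerate(_STAT_NAMES)
    ],
    ("cell_bottleneck", _cell_bottleneck),
    ("cell_n_compatible_fragments", lambda c: float(len(c.records))),
    ("cell_total_score", lambda c: sum(s for s, _ in c.records)),
    (
        "frac_junctions_expressed",
        lambda c: len(c.base.expressed_positions.get(c.cell, ()))
        / c.base.path.n_junctions,
    ),
    (
        "cell_fullchain",
        lambda c: 1.0 if c.cell in c.base.fullchain_cells else 0.0,
    ),
    (
        "cell_best_fragment_score",
        lambda c: max((s for s, _ in c.records), default=0.0),
    ),
    (
        "cell_best_fragment_fraction",
        lambda c: max((len(p) for _, p in c.records), default=0)
        / c.base.path.n_junctions,
    ),
    (
        "n_junctions_expressed",
        lambda c: float(len(c.base.expressed_positions.get(c.cell, ()))),
    ),
    ("cell_library_size", lambda c: 0.0),  # replaced below (needs index)
    ("cell_bottleneck_rank", _cell_bottleneck_rank),
    ("candidate_merging_score", lambda c: c.base.path.f_score),
]

assert len(CELL_FEATURES) == 21

GENERAL_NAMES = [name for name, _ in GENERAL_FEATURES]
CELL_NAMES = [name for name, _ in CELL_FEATURES]


def eligible_cells(
    path: CandidatePath, index: FragmentIndex
) -> list[str]:
    """Cells expressing >= 1 junction of the candidate (sorted)."""
    chain = path.chain
    cells: set[str] = set()
    for junction in chain.junctions:
        for frag in index.fragments_with_junction(
            chain.chrom, chain.strand, junction
        ):
            cells.add(frag.cell)
    return sorted(cells)


def general_feature_matrix(
    candidates: Sequence[CandidatePath], index: FragmentIndex
) -> pd.DataFrame:
    """One row per candidate (30 columns), indexed by candidate id."""
    rows = []
    for path in candidates:
        ctx = _build_context(path, index)
        rows.append([fn(ctx) for _, fn in GENERAL_FEATURES])
    frame = pd.DataFrame(
        rows, columns=GENERAL_NAMES, index=[p.id for p in candidates]
    )
    frame.index.name = "candidate_id"
    if len(frame) and not np.isfinite(frame.to_numpy()).all():
        raise AssertionError("non-finite general feature value")
    return frame


def cell_feature_matrix(
    candidates: Sequence[CandidatePath], index: FragmentIndex
) -> pd.DataFrame:
    """One row per eligible (candidate, cell) pair: 30 general + 21
    cell-specific columns, MultiIndex (candidate_id, cell)."""
    general = general_feature_matrix(candidates, index)
    rows = []
    keys = []
    for path in candidates:
        ctx = _build_context(path, index)
        g_row = general.loc[path.id].to_numpy()
        for cell in eligible_cells(path, index):
            cc = _build_cell_context(ctx, cell)
            values = [fn(cc) for _, fn in CELL_FEATURES]
            values[CELL_NAMES.index("cell_library_size")] = float(
                index.fragments_per_cell.get(cell, 0)
            )
            rows.append(np.concatenate([g_row, values]))
            keys.append((path.id, cell))
    frame = pd.DataFrame(
        rows,
        columns=GENERAL_NAMES + CELL_NAMES,
        index=pd.MultiIndex.from_tuples(
            keys or [], names=["candidate_id", "cell"]
        ),
    )
    return frame


def assemble_feature_matrix(
    candidates: Sequence[CandidatePath],
    index: FragmentIndex,
    mode: str,
) -> pd.DataFrame:
    """Feature table for *mode* ``"general"`` (candidate rows, 30 columns)
    or ``"specific"`` (eligible pair rows, 51 columns)."""
    if mode == "general":
        return general_feature_matrix(candidates, index)
    if mode == "specific":
        return cell_feature_matrix(candidates, index)
    raise ValueError(f"unknown feature mode: {mode!r}")


def write_feature_tsv(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        out.write(f"# feature schema {SCHEMA_VERSION}\n")
        frame.to_csv(out, sep="\t")
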