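"""Merging-score path search over the fragment graph.

A path ``p`` through a component represents a candidate full-length
transcript whose chain is the conflict-free merge of its vertices' chains.
Paths are ranked by the merging score

    F(p) = BJ(p) * NJ(p)

where ``NJ(p)`` is the number of junctions of the merged chain and
``BJ(p)`` is the bottleneck junction score: the minimum over junctions
``j`` of ``J(j, p)``, the summed scores of all transcript fragments (from
any cell) that contain ``j`` and are compatible with ``p``. A fragment is
compatible with ``p`` when it shares at least one junction with ``p`` and
none of its junctions conflicts with ``p`` — a conflict being a junction
absent from the chain whose intron interval overlaps one of the chain's
introns. Maximizing the bottleneck demands support for every junction
(discouraging chimeras), while the junction count rewards extension of
fragments into full-length transcripts.

The search processes each component in topological order, keeping the top
``pn`` paths per vertex (min-heap semantics) and the top ``pc`` per
component. F is not prefix-monotone — appending junctions can change which
fragments are compatible — so the score of every extension is recomputed
against the full merged chain rather than updated incrementally; the caps
are the heuristic making this affordable.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

from .fragment_graph import FragmentGraph, topological_order
from .gtf_io import (
    CellAssembly,
    Exon,
    IntronChain,
    Junction,
    TranscriptFragment,
)

__all__ = [
    "SearchParams",
    "FragmentIndex",
    "ChainSupport",
    "CandidatePath",
    "is_compatible",
    "junction_score",
    "merging_score",
    "chain_support",
    "search_component",
    "search_all",
    "write_candidate_tsv",
]


@dataclass(frozen=True)
class SearchParams:
    """Path-search caps: ``pn`` paths kept per vertex, ``pc`` per
    component. ``None`` disables a cap (exhaustive mode)."""

    pn: int | None = 15
    pc: int | None = 100

    def __post_init__(self) -> None:
        if self.pn is not None and self.pn < 1:
            raise ValueError("pn must be >= 1")
        if self.pc is not None and self.pc < 1:
            raise ValueError("pc must be >= 1")


@dataclass(frozen=True)
class _IndexedFragment:
    cell: str
    id: str
    score: float
    junctions: tuple[Junction, ...]
    first_exon_start: int
    last_exon_end: int


class FragmentIndex:
    """All input fragments indexed by (chrom, strand, junction) for fast
    junction-score queries."""

    def __init__(self, assemblies: Sequence[CellAssembly]):
        self._by_junction: dict[tuple, list[int]] = {}
        self._fragments: list[_IndexedFragment] = []
        self._support_cache: dict[tuple, "ChainSupport"] = {}
        self.cells: list[str] = [a.cell for a in assemblies]
        self.fragments_per_cell: dict[str, int] = {
            a.cell: len(a.fragments) for a in assemblies
        }
        for assembly in assemblies:
            for frag in assembly.fragments:
                self._add(frag)

    def _add(self, frag: TranscriptFragment) -> None:
        chain = frag.chain
        idx = len(self._fragments)
        self._fragments.append(
            _IndexedFragment(
                cell=frag.cell,
                id=frag.id,
                score=frag.score,
                junctions=chain.junctions,
                first_exon_start=frag.exons[0][0],
                last_exon_end=frag.exons[-1][1],
            )
        )
        key = (frag.chrom, frag.strand)
        for junction in chain.junctions:
            self._by_junction.setdefault(key + junction, []).append(idx)

    def fragments_with_junction(
        self, chrom: str, strand: str, junction: Junction
    ) -> list[_IndexedFragment]:
        return [
            self._fragments[i]
            for i in self._by_junction.get((chrom, strand) + junction, ())
        ]

    def support(self, chain: IntronChain) -> "ChainSupport":
        """Memoized :func:`chain_support`; the score of a merged chain
        depends only on the chain, so identical chains reached through
        different vertex sequences share one computation."""
        key = (chain.chrom, chain.strand, chain.junctions)
        hit = self._support_cache.get(key)
        if hit is None:
            hit = chain_support(chain, self)
            self._support_cache[key] = hit
        return hit

    def candidates_for_chain(self, chain: IntronChain) -> list[_IndexedFragment]:
        """Fragments sharing >= 1 junction with *chain* (deduplicated,
        input order)."""
        seen: set[int] = set()
        out: list[_IndexedFragment] = []
        key = (chain.chrom, chain.strand)
        for junction in chain.junctions:
            for i in self._by_junction.get(key + junction, ()):
                if i not in seen:
                    seen.add(i)
                    out.append(self._fragments[i])
        return out


def _conflicts(
    junctions: tuple[Junction, ...],
    chain_set: frozenset[Junction],
    intron_starts: list[int],
    introns: tuple[tuple[int, int], ...],
) -> bool:
    for junction in junctions:
        if junction in chain_set:
            continue
        a, b = junction[0] + 1, junction[1] - 1  # this fragment's intron
        pos = bisect_left(intron_starts, a)
        if pos > 0 and introns[pos - 1][1] >= a:
            return True
        if pos < len(introns) and introns[pos][0] <= b:
            return True
    return False


def is_compatible(
    fragment_chain: IntronChain, path_chain: IntronChain
) -> bool:
    """True iff the fragment shares >= 1 junction with the path and has no
    junction whose intron overlaps a path intron without being identical."""
    if fragment_chain.key != path_chain.key:
        return False
    chain_set = frozenset(path_chain.junctions)
    if not any(j in chain_set for j in fragment_chain.junctions):
        return False
    introns = path_chain.introns()
    starts = [s for s, _ in introns]
    return not _conflicts(fragment_chain.junctions, chain_set, starts, introns)


@dataclass(frozen=True)
class ChainSupport:
    """Everything the merging score and the feature blocks need about one
    merged chain: the per-junction scores and the compatible fragments."""

    chain: IntronChain
    #: J(j, p) per junction position, summed over all cells
    junction_scores: tuple[float, ...]
    bottleneck: float
    #: (cell, fragment id, score, covered junction positions) per
    #: compatible fragment
    compatible: tuple[tuple[str, str, float, tuple[int, ...]], ...]

    @property
    def n_junctions(self) -> int:
        return len(self.chain)

    @property
    def f_score(self) -> float:
        return self.bottleneck * self.n_junctions


def chain_support(chain: IntronChain, index: FragmentIndex) -> ChainSupport:
    """Score a merged chain from scratch against all input fragments."""
    chain_set = frozenset(chain.junctions)
    position = {j: k for k, j in enumerate(chain.junctions)}
    introns = chain.introns()
    starts = [s for s, _ in introns]

    j_scores = [0.0] * len(chain)
    compatible = []
    for frag in index.candidates_for_chain(chain):
        if _conflicts(frag.junctions, chain_set, starts, introns):
            continue
        positions = tuple(
            position[j] for j in frag.junctions if j in chain_set
        )
        for k in positions:
            j_scores[k] += frag.score
        compatible.append((frag.cell, frag.id, frag.score, positions))
    return ChainSupport(
        chain=chain,
        junction_scores=tuple(j_scores),
        bottleneck=min(j_scores) if j_scores else 0.0,
        compatible=tuple(compatible),
    )


def junction_score(
    junction: Junction, chain: IntronChain, index: FragmentIndex
) -> float:
    """J(j, p): summed scores of compatible fragments containing *junction*."""
    if junction not in chain.junctions:
        raise ValueError(f"junction {junction} not on the path")
    support = chain_support(chain, index)
    return support.junction_scores[chain.junctions.index(junction)]


def merging_score(chain: IntronChain, index: FragmentIndex) -> float:
    """F(p) = BJ(p) * NJ(p) computed from scratch on the merged chain."""
    return chain_support(chain, index).f_score


@dataclass(frozen=True)
class CandidatePath:
    """A path through one component: a candidate full-length transcript."""

    id: str
    chain: IntronChain
    vertex_indices: tuple[int, ...]  # indices into the component
    overlaps: tuple[int, ...]  # overlap_len along consecutive edges
    support: ChainSupport
    component: int = -1
    exons: tuple[Exon, ...] = ()

    @property
    def chrom(self) -> str:
        return self.chain.chrom

    @property
    def strand(self) -> str:
        return self.chain.strand

    @property
    def n_junctions(self) -> int:
        return len(self.chain)

    @property
    def bottleneck(self) -> float:
        return self.support.bottleneck

    @property
    def f_score(self) -> float:
        return self.support.f_score

    @property
    def supporting_cells(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _, _, _ in self.support.compatible}))


def _rank_key(f_score: float, junctions: tuple, vertices: tuple):
    # best first: F desc, NJ desc, chain lexicographic asc, vertices asc
    return (-f_score, -len(junctions), junctions, vertices)


@dataclass(frozen=True)
class _DpPath:
    junctions: tuple[Junction, ...]
    vertices: tuple[int, ...]
    overlaps: tuple[int, ...]
    support: ChainSupport

    @property
    def f_score(self) -> float:
        return self.support.f_score


def search_component(
    component: FragmentGraph,
    params: SearchParams,
    index: FragmentIndex,
) -> list[CandidatePath]:
    """Enumerate the top-``pc`` merging-score paths of one component.

    Vertices are processed in topological order. Each vertex seeds its own
    single-vertex path and extends every kept path of each predecessor
    along the connecting edge, rescoring the full merged chain. Only the
    ``pn`` best paths per vertex are retained.
    """
    order = topological_order(component)
    key = component.vertices[order[0]].chain.key if order else None
    paths_at: dict[int, list[_DpPath]] = {}

    for v in order:
        v_chain = component.vertices[v].chain
        entries: list[_DpPath] = [
            _DpPath(
                junctions=v_chain.junctions,
                vertices=(v,),
                overlaps=(),
                support=index.support(v_chain),
            )
        ]
        for u in component.digraph.predecessors(v):
            k = component.digraph.edges[u, v]["overlap_len"]
            for prev in paths_at[u]:
                merged = prev.junctions + v_chain.junctions[k:]
                chain = IntronChain(key[0], key[1], merged)
                entries.append(
                    _DpPath(
                        junctions=merged,
                        vertices=prev.vertices + (v,),
                        overlaps=prev.overlaps + (k,),
                        support=index.support(chain),
                    )
                )
        entries.sort(key=lambda p: _rank_key(p.f_score, p.junctions, p.vertices))
        if params.pn is not None:
            entries = entries[: params.pn]
        paths_at[v] = entries

    all_paths = [p for entries in paths_at.values() for p in entries]
    all_paths.sort(key=lambda p: _rank_key(p.f_score, p.junctions, p.vertices))
    if params.pc is not None:
        all_paths = all_paths[: params.pc]
    return [
        CandidatePath(
            id="",
            chain=p.support.chain,
            vertex_indices=p.vertices,
            overlaps=p.overlaps,
            support=p.support,
        )
        for p in all_paths
    ]


def _terminal_exons(
    chain: IntronChain, index: FragmentIndex
) -> tuple[Exon, ...]:
    """Exon list for a merged chain. Internal exons are fixed by the
    junctions; terminal boundaries take the extremal coordinates over
    supporting fragments that start (end) with the chain's first (last)
    junction, preserving all observed exonic sequence."""
    first_j, last_j = chain.junctions[0], chain.junctions[-1]
    starts = [
        f.first_exon_start
        for f in index.fragments_with_junction(chain.chrom, chain.strand, first_j)
        if f.junctions[0] == first_j
    ]
    ends = [
        f.last_exon_end
        for f in index.fragments_with_junction(chain.chrom, chain.strand, last_j)
        if f.junctions[-1] == last_j
    ]
    first_start = min(starts) if starts else max(first_j[0] - 1, 1)
    last_end = max(ends) if ends else last_j[1] + 1
    exons: list[Exon] = []
    prev_acceptor = first_start
    for donor, acceptor in chain.junctions:
        exons.append((prev_acceptor, donor))
        prev_acceptor = acceptor
    exons.append((prev_acceptor, last_end))
    return tuple(exons)


def search_all(
    graph_components: Sequence[FragmentGraph],
    params: SearchParams,
    index: FragmentIndex,
) -> list[CandidatePath]:
    """Union of per-component searches, deduplicated by merged chain.

    The merging score depends only on the merged chain, so duplicate chains
    (reachable through different vertex sequences or components) tie in F;
    the first occurrence in the deterministic component/rank order is kept.
    """
    by_chain: dict[IntronChain, CandidatePath] = {}
    for comp_idx, component in enumerate(graph_components):
        for path in search_component(component, params, index):
            prior = by_chain.get(path.chain)
            if prior is not None and prior.f_score >= path.f_score:
                continue
            by_chain[path.chain] = CandidatePath(
                id="",
                chain=path.chain,
                vertex_indices=path.vertex_indices,
                overlaps=path.overlaps,
                support=path.support,
                component=comp_idx,
            )
    ordered = sorted(
        by_chain.values(),
        key=lambda p: (p.chrom, p.strand, p.chain.junctions),
    )
    return [
        CandidatePath(
            id=f"cand.{n + 1}",
            chain=p.chain,
            vertex_indices=p.vertex_indices,
            overlaps=p.overlaps,
            support=p.support,
            component=p.component,
            exons=_terminal_exons(p.chain, index),
        )
        for n, p in enumerate(ordered)
    ]


def write_candidate_tsv(candidates: Sequence[CandidatePath], path) -> None:
    """Sidecar table: one row per candidate with its search statistics."""
    with open(path, "w") as out:
        out.write(
            "candidate_id\tcomponent\tchrom\tstrand\tn_junctions\t"
            "bottleneck\tmerging_score\tn_supporting_cells\tfragment_ids\n"
        )
        for c in candidates:
            frag_ids = ";".join(
                f"{cell}:{fid}" for cell, fid, _, _ in c.support.compatible
            )
            out.write(
                f"{c.id}\t{c.component}\t{c.chrom}\t{c.strand}\t"
                f"{c.n_junctions}\t{c.bottleneck:.6f}\t{c.f_score:.6f}\t"
                f"{len(c.supporting_cells)}\t{frag_ids}\n"
            )
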