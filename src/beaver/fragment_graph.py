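"""The transcript fragment graph.

Vertices are distinct intron chains observed in any cell's assembly; a
directed edge ``u -> v`` exists when some suffix of ``u``'s chain equals a
prefix of ``v``'s chain and ``v`` extends strictly beyond ``u`` on the
right. Walking an edge therefore merges the two chains without conflict,
which is how fragments truncated by coverage gaps in one cell are extended
with junctions observed in other cells.

Identical chains from different cells collapse into one vertex carrying all
(cell, fragment, score) supports: any path through per-fragment duplicate
vertices would yield the same merged chain, while deduplication guarantees
acyclicity and shrinks the path search. A chain entirely contained in
another receives no edge — merging would add nothing.

Every edge strictly increases the rightmost junction, so the graph is a
DAG by construction; this is asserted on every build. Weakly connected
components play the role of gene loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .gtf_io import CellAssembly, IntronChain

__all__ = [
    "GraphVertex",
    "FragmentGraph",
    "build_graph",
    "connected_components",
    "topological_order",
    "write_dot",
    "write_edge_tsv",
]


@dataclass(frozen=True)
class GraphVertex:
    """A deduplicated intron chain with its multi-cell support records."""

    chain: IntronChain
    #: (cell id, fragment id, score) for every input fragment with this chain
    supports: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if not self.supports:
            raise ValueError("vertex without supporting fragments")

    @property
    def total_score(self) -> float:
        return sum(s for _, _, s in self.supports)

    def sort_key(self):
        c = self.chain
        return (c.chrom, c.strand, c.junctions[0][0], len(c), self.supports[0][0])


@dataclass
class FragmentGraph:
    """DAG over chain vertices; ``overlap`` maps edges to overlap length."""

    vertices: list[GraphVertex]
    digraph: nx.DiGraph  # nodes are indices into ``vertices``

    @property
    def edges(self) -> list[tuple[int, int, int]]:
        return [
            (u, v, d["overlap_len"])
            for u, v, d in self.digraph.edges(data=True)
        ]

    def fragments(self) -> Iterable[tuple[str, str, float, IntronChain]]:
        for vertex in self.vertices:
            for cell, fid, score in vertex.supports:
                yield cell, fid, score, vertex.chain


def _suffix_prefix_overlap(
    u_chain: IntronChain, v_chain: IntronChain
) -> int | None:
    """Maximal k >= 1 with suffix_k(u) == prefix_k(v) and v extending
    strictly beyond u; None when no such k exists."""
    uj, vj = u_chain.junctions, v_chain.junctions
    first = vj[0]
    for i, junction in enumerate(uj):
        if junction != first:
            continue
        k = len(uj) - i
        # v must carry all of u's remaining junctions, plus more
        if len(vj) > k and vj[:k] == uj[i:]:
            return k
    return None


def build_graph(assemblies: Sequence[CellAssembly]) -> FragmentGraph:
    """Construct the fragment graph over all cells' assemblies."""
    by_chain: dict[IntronChain, list[tuple[str, str, float]]] = {}
    for assembly in assemblies:
        for frag in assembly.fragments:
            by_chain.setdefault(frag.chain, []).append(
                (frag.cell, frag.id, frag.score)
            )

    vertices = [
        GraphVertex(chain=chain, supports=tuple(sorted(sup)))
        for chain, sup in by_chain.items()
    ]
    vertices.sort(key=GraphVertex.sort_key)

    digraph = nx.DiGraph()
    digraph.add_nodes_from(range(len(vertices)))

    # index vertices of each (chrom, strand) by their first junction
    by_first: dict[tuple, list[int]] = {}
    for idx, vertex in enumerate(vertices):
        c = vertex.chain
        by_first.setdefault((c.chrom, c.strand, c.junctions[0]), []).append(idx)

    for u_idx, u in enumerate(vertices):
        uc = u.chain
        seen: set[int] = set()
        for i, junction in enumerate(uc.junctions):
            for v_idx in by_first.get((uc.chrom, uc.strand, junction), ()):
                if v_idx == u_idx or v_idx in seen:
                    continue
                k = _suffix_prefix_overlap(uc, vertices[v_idx].chain)
                if k is not None:
                    digraph.add_edge(u_idx, v_idx, overlap_len=k)
                    seen.add(v_idx)  # first hit = maximal k

    graph = FragmentGraph(vertices=vertices, digraph=digraph)
    _assert_invariants(graph)
    return graph


def _assert_invariants(graph: FragmentGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph.digraph):
        raise AssertionError("fragment graph contains a directed cycle")
    for u, v, k in graph.edges:
        uc = graph.vertices[u].chain
        vc = graph.vertices[v].chain
        if uc.key != vc.key:
            raise AssertionError("edge joins different (chrom, strand)")
        if uc.junctions[len(uc) - k :] != vc.junctions[:k] or len(vc) <= k:
            raise AssertionError("edge violates suffix/prefix overlap rule")


def connected_components(graph: FragmentGraph) -> list[FragmentGraph]:
    """Split into weakly connected components (isolated vertices become
    singletons); vertex order inside each component is preserved."""
    components = []
    for nodes in nx.weakly_connected_components(graph.digraph):
        idx = sorted(nodes)
        remap = {old: new for new, old in enumerate(idx)}
        sub = nx.DiGraph()
        sub.add_nodes_from(range(len(idx)))
        for u, v, d in graph.digraph.subgraph(idx).edges(data=True):
            sub.add_edge(remap[u], remap[v], **d)
        components.append(
            FragmentGraph(
                vertices=[graph.vertices[i] for i in idx], digraph=sub
            )
        )
    components.sort(key=lambda c: c.vertices[0].sort_key())
    return components


def topological_order(component: FragmentGraph) -> list[int]:
    """Deterministic topological order of vertex indices.

    Ties are broken by (chrom, first junction donor, chain length, first
    supporting cell id) so downstream path enumeration is reproducible.
    """
    keys = {i: component.vertices[i].sort_key() for i in component.digraph}
    return list(
        nx.lexicographical_topological_sort(
            component.digraph, key=lambda n: keys[n]
        )
    )


def write_dot(graph: FragmentGraph, path) -> None:
    """Debug export as GraphViz DOT."""
    with open(path, "w") as out:
        out.write("digraph fragments {\n")
        for i, vertex in enumerate(graph.vertices):
            label = ",".join(
                f"{d}-{a}" for d, a in vertex.chain.junctions
            )
            out.write(f'  v{i} [label="{label}\\n{len(vertex.supports)}x"];\n')
        for u, v, k in graph.edges:
            out.write(f'  v{u} -> v{v} [label="{k}"];\n')
        out.write("}\n")


def write_edge_tsv(graph: FragmentGraph, path) -> None:
    """Debug export of the edge list as TSV."""
    with open(path, "w") as out:
        out.write("source_chain\ttarget_chain\toverlap_len\n")
        for u, v, k in graph.edges:
            sc = ";".join(f"{d}-{a}" for d, a in graph.vertices[u].chain.junctions)
            tc = ";".join(f"{d}-{a}" for d, a in graph.vertices[v].chain.junctions)
            out.write(f"{sc}\t{tc}\t{k}\n")
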