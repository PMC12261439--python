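"""Independent oracles and hand-built micro-instances for the test suite.

Everything here deliberately avoids the package's own support/scoring code
paths: merging scores are recomputed with plain nested loops over interval
arithmetic, and path enumeration is a direct DFS over the DAG, so that
agreement between package and oracle is informative.
"""

from __future__ import annotations

import numpy as np

from beaver import (
    CellAssembly,
    IntronChain,
    TranscriptFragment,
    build_graph,
    connected_components,
)
from beaver.simulate import SimConfig, simulate_annotation, simulate_cells

CHROM, STRAND = "1", "+"

# well-separated junctions on a shared coordinate grid
J1, J2, J3, J4, J5 = (100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)
# JX overlaps J2's intron without equaling it
JX = (350, 450)


def frag(junctions, score, cell="c1", fid="t", chrom=CHROM, strand=STRAND):
    """Build a TranscriptFragment whose chain is exactly *junctions*."""
    junctions = list(junctions)
    exons = [(junctions[0][0] - 50, junctions[0][0])]
    for (d1, a1), nxt in zip(junctions, junctions[1:]):
        exons.append((a1, nxt[0]))
    exons.append((junctions[-1][1], junctions[-1][1] + 50))
    return TranscriptFragment(
        id=fid, cell=cell, chrom=chrom, strand=strand,
        exons=tuple(exons), score=score,
    )


def chain(junctions, chrom=CHROM, strand=STRAND) -> IntronChain:
    return IntronChain(chrom, strand, tuple(junctions))


def bf_merging_score(chain_junctions, fragments):
    """Brute-force (F, BJ, per-junction J) for a path chain.

    *fragments* is a list of (junction tuple, score). Compatibility and
    junction scores are evaluated with direct nested loops.
    """
    def intron(j):
        return (j[0] + 1, j[1] - 1)

    def overlaps(a, b):
        return a[0] <= b[1] and b[0] <= a[1]

    compat = []
    for junctions, score in fragments:
        if not any(j in chain_junctions for j in junctions):
            continue
        conflict = any(
            j not in chain_junctions and overlaps(intron(j), intron(cj))
            for j in junctions
            for cj in chain_junctions
        )
        if not conflict:
            compat.append((junctions, score))
    j_scores = [
        sum(s for js, s in compat if j in js) for j in chain_junctions
    ]
    bj = min(j_scores)
    return bj * len(j_scores), bj, j_scores


#: (name, fragments as (junctions, score), path junctions,
#:  expected (NJ, BJ, F)) — all expectations derived by hand
MICRO_CASES = [
    ("single_fragment_single_junction",
     [((J1,), 0.5)], (J1,), (1, 0.5, 0.5)),
    ("two_fragments_shared_junction",
     [((J1,), 0.5), ((J1, J2), 0.4)], (J1, J2), (2, 0.4, 0.8)),
    ("superchain_fragment_compatible_with_subpath",
     [((J1,), 0.5), ((J1, J2), 0.4)], (J1,), (1, 0.9, 0.9)),
    ("conflicting_fragment_contributes_nothing",
     [((J1, J2), 0.4), ((J1, JX), 0.8)], (J1, J2), (2, 0.4, 0.8)),
    ("four_fragment_chain_merge",
     [((J1, J2), 0.5), ((J2, J3), 0.6), ((J3, J4), 0.7), ((J4, J5), 0.8)],
     (J1, J2, J3, J4, J5), (5, 0.5, 2.5)),
    ("disjoint_fragment_ignored",
     [((J1,), 0.5), ((J5,), 0.9)], (J1,), (1, 0.5, 0.5)),
    ("unsupported_junction_zeroes_bottleneck",
     [((J1,), 0.5)], (J1, J2), (2, 0.0, 0.0)),
    ("duplicate_chain_scores_add",
     [((J1, J2), 0.3), ((J1, J2), 0.2)], (J1, J2), (2, 0.5, 1.0)),
    ("fragment_extending_beyond_path_still_counts",
     [((J1, J2, J3), 0.4)], (J1, J2), (2, 0.4, 0.8)),
    ("overlapping_windows_double_middle_junction",
     [((J1, J2), 0.5), ((J2, J3), 0.5)], (J1, J2, J3), (3, 0.5, 1.5)),
    ("saturated_scores_sum_across_cells",
     [((J1, J2), 1.0), ((J1, J2), 1.0), ((J1, J2), 1.0)],
     (J1, J2), (2, 3.0, 6.0)),
]


def micro_assemblies(fragments):
    """Wrap (junctions, score) pairs into per-cell assemblies (one cell
    per fragment so duplicate chains stay distinct fragments)."""
    return [
        CellAssembly(
            cell=f"c{i}",
            fragments=[frag(js, s, cell=f"c{i}", fid=f"t{i}")],
        )
        for i, (js, s) in enumerate(fragments)
    ]


def enumerate_paths(component):
    """All directed paths (as vertex index tuples) in a DAG component."""
    paths = []

    def extend(path):
        paths.append(tuple(path))
        for nxt in sorted(component.digraph.successors(path[-1])):
            extend(path + [nxt])

    for v in sorted(component.digraph.nodes):
        extend([v])
    return paths


def merge_vertex_chains(component, path):
    """Merged junction tuple of a vertex path, by maximal suffix/prefix
    matching (independent of the package's edge bookkeeping)."""
    merged = list(component.vertices[path[0]].chain.junctions)
    for v in path[1:]:
        vj = component.vertices[v].chain.junctions
        k = 0
        for cand in range(min(len(merged), len(vj)), 0, -1):
            if tuple(merged[-cand:]) == vj[:cand]:
                k = cand
                break
        assert k >= 1, "path is not connected by chain overlap"
        merged.extend(vj[k:])
    return tuple(merged)


def random_components(n_needed, base_seed, max_vertices=12):
    """Random multi-cell fixtures chopped into graph components with
    <= *max_vertices* vertices.

    Yields (component, same-locus fragment list for brute-force scoring,
    FragmentIndex over the whole originating fixture).
    """
    from beaver import FragmentIndex

    out = []
    seed = base_seed
    while len(out) < n_needed:
        config = SimConfig(
            n_genes=6, n_cells=3, dropout_prob=0.15, decoy_rate=0.1,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        isoforms = simulate_annotation(config, rng)
        _truth, assemblies = simulate_cells(isoforms, config, rng)
        index = FragmentIndex(assemblies)
        by_key: dict[tuple, list] = {}
        for a in assemblies:
            for f in a.fragments:
                by_key.setdefault((f.chrom, f.strand), []).append(
                    (f.chain.junctions, f.score)
                )
        graph = build_graph(assemblies)
        for comp in connected_components(graph):
            if len(comp.vertices) <= max_vertices:
                key = comp.vertices[0].chain.key
                out.append((comp, by_key.get(key, []), index))
        seed += 1
    return out[:n_needed]
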