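"""Synthetic scRNA-seq assembly fixtures.

The generator plants a multi-isoform annotation, draws per-cell expressed
transcripts, and emits per-cell input assemblies that mimic what a
short-read single-cell assembler produces: intron chains *fragmented* into
contiguous sub-chains (coverage gaps), whole fragments lost to *dropout*,
confidence scores that correlate with truth but carry uniform noise, and
*decoy* fragments whose single perturbed acceptor creates a conflicting
junction — precisely the artifact the compatibility predicate must reject.

Construction guarantees worth knowing:

* isoforms of one gene are built from shared exon slots, so distinct
  isoforms share junctions and end up in one graph component;
* consecutive fragments of an expressed isoform overlap by at least one
  junction, so with zero dropout the true chain is reconstructible as a
  path through the fragment graph;
* fragment scores are ``clamp(signal * truth_indicator + U(0, noise), 0, 1)``,
  giving truth-derived fragments stochastically higher scores than decoys
  — the learnable signal for the random forests;
* genes alternate between low-numbered (training) and high-numbered
  (held-out) chromosomes so the chromosome split is always exercised.

Everything is driven by one ``numpy`` generator seeded from the config;
the same seed yields byte-identical GTF output.

What this emulates — and what it does not: real Smart-seq3 inputs have
coverage-dependent fragmentation, correlated dropout, PCR artifacts and
unannotated transcription; here fragmentation, dropout and noise are
independent draws. Passing tests demonstrate the machinery recovers
planted structure under these idealized conditions, not performance on
real libraries.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from .gtf_io import (
    CellAssembly,
    Exon,
    IntronChain,
    TranscriptFragment,
)

__all__ = [
    "SimConfig",
    "IsoformRecord",
    "SimResult",
    "simulate_annotation",
    "simulate_cells",
    "make_end_to_end_fixture",
    "FIXTURE_SCALES",
]

#: chromosomes alternate across the default 1–9 train split
_CHROM_CYCLE = [str(c) for pair in zip(range(1, 10), range(10, 19)) for c in pair]


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 10
    n_cells: int = 5
    isoforms_per_gene: tuple[int, int] = (2, 3)
    exons_per_isoform: tuple[int, int] = (3, 7)
    #: probability each (isoform, cell) is expressed
    expression_prob: float = 0.5
    #: expected number of fragments an expressed transcript is cut into
    mean_fragments: float = 2.0
    #: junction-overlap length range between consecutive fragments
    overlap_range: tuple[int, int] = (1, 2)
    #: probability an individual fragment is lost
    dropout_prob: float = 0.1
    #: probability a non-expressed (isoform, cell) emits a decoy fragment
    decoy_rate: float = 0.05
    #: score = clamp(signal * truth + U(0, noise_span), 0, 1)
    signal: float = 0.4
    noise_span: float = 0.55
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.expression_prob, self.dropout_prob, self.decoy_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.isoforms_per_gene[0] < 1 or self.exons_per_isoform[0] < 2:
            raise ValueError("degenerate isoform/exon ranges")
        if self.overlap_range[0] < 1:
            raise ValueError("fragment overlaps must be >= 1 junction")


@dataclass(frozen=True)
class IsoformRecord:
    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]

    @property
    def chain(self) -> IntronChain:
        junctions = tuple(
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
        )
        return IntronChain(self.chrom, self.strand, junctions)


@dataclass
class SimResult:
    config: SimConfig
    isoforms: list[IsoformRecord]
    per_cell_truth: dict[str, set[IntronChain]]
    assemblies: list[CellAssembly]

    @property
    def annotation_chains(self) -> set[IntronChain]:
        return {iso.chain for iso in self.isoforms}

    def write(self, outdir: str | os.PathLike) -> None:
        """Write reference GTF, per-cell input GTFs, truth TSV, config."""
        outdir = os.fspath(outdir)
        os.makedirs(os.path.join(outdir, "cells"), exist_ok=True)
        _write_isoform_gtf(self.isoforms, os.path.join(outdir, "reference.gtf"))
        for assembly in self.assemblies:
            _write_assembly_gtf(
                assembly, os.path.join(outdir, "cells", f"{assembly.cell}.gtf")
            )
        chain_ids = {iso.chain: iso.transcript for iso in self.isoforms}
        with open(os.path.join(outdir, "truth.tsv"), "w") as out:
            out.write("cell\ttranscript\n")
            for cell in sorted(self.per_cell_truth):
                for chain in sorted(self.per_cell_truth[cell]):
                    out.write(f"{cell}\t{chain_ids[chain]}\n")
        with open(os.path.join(outdir, "config.json"), "w") as out:
            json.dump(asdict(self.config), out, indent=2, default=list)


def _write_isoform_gtf(isoforms: Sequence[IsoformRecord], path) -> None:
    with open(path, "w") as out:
        out.write("# synthetic reference annotation\n")
        for iso in isoforms:
            attrs = f'gene_id "{iso.gene}"; transcript_id "{iso.transcript}";'
            span = (iso.exons[0][0], iso.exons[-1][1])
            out.write(
                f"{iso.chrom}\tsim\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                f"{iso.strand}\t.\t{attrs}\n"
            )
            for start, end in iso.exons:
                out.write(
                    f"{iso.chrom}\tsim\texon\t{start}\t{end}\t.\t"
                    f"{iso.strand}\t.\t{attrs}\n"
                )


def _write_assembly_gtf(assembly: CellAssembly, path) -> None:
    with open(path, "w") as out:
        out.write(f"# synthetic input assembly, cell {assembly.cell}\n")
        for frag in assembly.fragments:
            attrs = (
                f'gene_id "{frag.id}"; transcript_id "{frag.id}"; '
                f'cov "{frag.score:.6f}";'
            )
            span = (frag.exons[0][0], frag.exons[-1][1])
            out.write(
                f"{frag.chrom}\tsim\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                f"{frag.strand}\t.\t{attrs}\n"
            )
            for start, end in frag.exons:
                out.write(
                    f"{frag.chrom}\tsim\texon\t{start}\t{end}\t.\t"
                    f"{frag.strand}\t.\t{attrs}\n"
                )


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[IsoformRecord]:
    """Plant genes whose isoforms are subsets of shared exon slots.

    Every isoform keeps the first two slots, so all isoforms of a gene
    share the first junction (and hence land in one graph component);
    distinct isoforms differ in which later slots they retain.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo_iso, hi_iso = config.isoforms_per_gene
    lo_ex, hi_ex = config.exons_per_isoform
    n_slots = hi_ex + 2
    per_chrom_offset: dict[str, int] = {}
    isoforms: list[IsoformRecord] = []

    for g in range(config.n_genes):
        chrom = _CHROM_CYCLE[g % len(_CHROM_CYCLE)]
        slot = per_chrom_offset.get(chrom, 0)
        per_chrom_offset[chrom] = slot + 1
        base = 100_000 + slot * 1_000_000
        strand = "+" if rng.random() < 0.5 else "-"

        # shared exon slots for the whole gene
        slots: list[Exon] = []
        pos = base
        for _ in range(n_slots):
            length = int(rng.integers(80, 301))
            slots.append((pos, pos + length - 1))
            pos += length + int(rng.integers(100, 1001))

        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        seen: set[tuple] = set()
        for t in range(n_iso):
            for _attempt in range(25):
                n_ex = int(rng.integers(lo_ex, hi_ex + 1))
                extra = sorted(
                    rng.choice(
                        np.arange(2, n_slots), size=n_ex - 2, replace=False
                    ).tolist()
                )
                chosen = tuple([0, 1] + extra)
                if chosen not in seen:
                    seen.add(chosen)
                    break
            else:
                continue
            isoforms.append(
                IsoformRecord(
                    gene=f"gene{g}",
                    transcript=f"gene{g}.t{t}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(slots[i] for i in chosen),
                )
            )
    return isoforms


def _breakpoints(
    m: int, config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Canonical fragile positions of one isoform's chain, as
    (cut position, overlap length) pairs.

    Coverage gaps concentrate at the same weakly covered stretches of a
    transcript in every cell, so each isoform draws its candidate cut
    positions — and the junction overlap left at each — once; per-cell
    fragmentation then samples a subset of these cuts. This keeps the
    vocabulary of distinct fragment windows per isoform small, which is
    what makes the planted chain recoverable under the default
    per-component path caps."""
    size = min(m - 1, max(1, int(round(config.mean_fragments))))
    if size <= 0 or m <= 1:
        return []
    lo_ov, hi_ov = config.overlap_range
    positions = sorted(
        rng.choice(np.arange(1, m), size=size, replace=False).tolist()
    )
    return [(p, int(rng.integers(lo_ov, hi_ov + 1))) for p in positions]


def _cut_chain(
    m: int,
    breakpoints: list[tuple[int, int]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Split junction positions 0..m-1 into contiguous windows where
    consecutive windows overlap by >= 1 junction; cuts and overlaps come
    from the isoform's canonical breakpoint set."""
    n_frags = 1 + int(rng.poisson(max(config.mean_fragments - 1.0, 0.0)))
    n_frags = min(n_frags, len(breakpoints) + 1)
    if n_frags <= 1:
        return [(0, m - 1)]
    chosen = sorted(
        rng.choice(len(breakpoints), size=n_frags - 1, replace=False).tolist()
    )
    cuts = [breakpoints[i] for i in chosen]
    bounds = [0] + [pos for pos, _ in cuts] + [m]
    windows = []
    for j in range(n_frags):
        start, end = bounds[j], bounds[j + 1] - 1
        if j > 0:
            overlap = cuts[j - 1][1]
            start = max(0, start - overlap)
        windows.append((start, end))
    return windows


def _fragment_exons(
    iso: IsoformRecord,
    window: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[Exon, ...]:
    """Exons for the fragment covering junction positions [a, b]; internal
    cut points get truncated terminal exons (incomplete first/last exons)."""
    a, b = window
    m = len(iso.exons) - 1
    exons = list(iso.exons[a : b + 2])
    if a > 0:
        s, e = exons[0]
        trim = int(rng.integers(0, min(100, e - s) + 1))
        exons[0] = (min(e, s + trim), e)
    if b < m - 1:
        s, e = exons[-1]
        trim = int(rng.integers(0, min(100, e - s) + 1))
        exons[-1] = (s, max(s, e - trim))
    return tuple(exons)


def _decoy_fragment(
    iso: IsoformRecord,
    fid: str,
    cell: str,
    score: float,
    all_acceptors: set[int],
    rng: np.random.Generator,
) -> TranscriptFragment | None:
    """A short window of *iso* with one acceptor shifted into the exon —
    a junction conflicting with the true chain."""
    m = len(iso.exons) - 1
    length = int(rng.integers(1, min(3, m) + 1))
    a = int(rng.integers(0, m - length + 1))
    exons = list(iso.exons[a : a + length + 1])
    # perturb the acceptor of the first junction in the window
    s, e = exons[1]
    if e - s < 10:
        return None
    delta = int(rng.integers(8, min(20, e - s)))
    new_start = s + delta
    while new_start in all_acceptors and new_start < e:
        new_start += 1
    if new_start >= e:
        return None
    exons[1] = (new_start, e)
    return TranscriptFragment(
        id=fid,
        cell=cell,
        chrom=iso.chrom,
        strand=iso.strand,
        exons=tuple(exons),
        score=score,
    )


def simulate_cells(
    isoforms: Sequence[IsoformRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, set[IntronChain]], list[CellAssembly]]:
    """Draw per-cell truths and emit fragmented, noisily scored inputs."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    all_acceptors = {
        s for iso in isoforms for s, _ in iso.exons[1:]
    }
    breakpoints = {
        iso.transcript: _breakpoints(len(iso.chain), config, rng)
        for iso in isoforms
    }
    truth: dict[str, set[IntronChain]] = {}
    assemblies: list[CellAssembly] = []

    for c in range(config.n_cells):
        cell = f"cell{c:03d}"
        truth[cell] = set()
        fragments: list[TranscriptFragment] = []
        counter = 0
        for iso in isoforms:
            expressed = rng.random() < config.expression_prob
            if expressed:
                truth[cell].add(iso.chain)
                m = len(iso.chain)
                for window in _cut_chain(
                    m, breakpoints[iso.transcript], config, rng
                ):
                    score = float(
                        np.clip(
                            config.signal
                            + rng.uniform(0.0, config.noise_span),
                            0.0,
                            1.0,
                        )
                    )
                    dropped = rng.random() < config.dropout_prob
                    if dropped:
                        continue
                    counter += 1
                    fragments.append(
                        TranscriptFragment(
                            id=f"{cell}.f{counter}",
                            cell=cell,
                            chrom=iso.chrom,
                            strand=iso.strand,
                            exons=_fragment_exons(iso, window, rng),
                            score=score,
                        )
                    )
            elif rng.random() < config.decoy_rate:
                score = float(
                    np.clip(rng.uniform(0.0, config.noise_span), 0.0, 1.0)
                )
                counter += 1
                decoy = _decoy_fragment(
                    iso,
                    f"{cell}.f{counter}",
                    cell,
                    score,
                    all_acceptors,
                    rng,
                )
                if decoy is not None:
                    fragments.append(decoy)
        assemblies.append(CellAssembly(cell=cell, fragments=fragments))
    return truth, assemblies


FIXTURE_SCALES: Mapping[str, SimConfig] = {
    "tiny": SimConfig(n_genes=3, n_cells=3),
    "small": SimConfig(n_genes=50, n_cells=10),
    "medium": SimConfig(n_genes=300, n_cells=30, expression_prob=0.35),
}


def make_end_to_end_fixture(
    scale: str = "tiny",
    seed: int = 1,
    outdir: str | os.PathLike | None = None,
    **overrides,
) -> SimResult:
    """Build a complete fixture at a named scale.

    ``tiny`` (3 genes x 3 cells) backs unit tests, ``small`` (50 x 10)
    integration tests, ``medium`` (300 x 30) the end-to-end evaluation.
    Keyword overrides replace individual config fields (e.g.
    ``dropout_prob=0`` for planted-path recovery checks).
    """
    base = FIXTURE_SCALES[scale]
    config = SimConfig(**{**asdict(base), **overrides, "seed": seed})
    rng = np.random.default_rng(config.seed)
    isoforms = simulate_annotation(config, rng)
    truth, assemblies = simulate_cells(isoforms, config, rng)
    result = SimResult(
        config=config,
        isoforms=isoforms,
        per_cell_truth=truth,
        assemblies=assemblies,
    )
    if outdir is not None:
        result.write(outdir)
    return result
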