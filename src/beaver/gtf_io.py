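"""Read and write per-cell scored GTF assemblies.

Input to the meta-assembler is one GTF file per cell, each multi-exon
transcript carrying a normalized confidence score in [0, 1] (attribute
``cov`` by default). Single-exon transcripts are excluded throughout: the
method extends fragmented intron chains, and a transcript without a junction
has no chain to extend.

Coordinates follow the GTF convention: 1-based, inclusive. A junction is
stored as ``(donor, acceptor)`` = (last base of the upstream exon, first
base of the downstream exon); the spliced-out intron is the closed interval
``[donor + 1, acceptor - 1]``. Intron-chain equality is exact integer
comparison within identical (chromosome, strand).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

__all__ = [
    "Exon",
    "Junction",
    "IntronChain",
    "TranscriptFragment",
    "CellAssembly",
    "ScoredTranscript",
    "ScoredAssembly",
    "GtfParseError",
    "read_cell_gtf",
    "read_reference_chains",
    "intron_chain_of",
    "write_scored_gtf",
    "write_candidate_gtf",
]

#: an exon as (start, end), 1-based inclusive, start <= end
Exon = tuple[int, int]

#: a splice junction as (donor, acceptor): donor = last exonic base of the
#: upstream exon, acceptor = first exonic base of the downstream exon
Junction = tuple[int, int]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass(frozen=True, order=True)
class IntronChain:
    """Ordered list of junctions of a multi-exon transcript.

    Two transcripts are considered the same isoform structure exactly when
    their chains compare equal; terminal exon boundaries are deliberately
    not part of the chain (first/last exons of fragments may be incomplete).
    """

    chrom: str
    strand: str
    junctions: tuple[Junction, ...]

    def __post_init__(self) -> None:
        if len(self.junctions) < 1:
            raise ValueError("an intron chain needs at least one junction")
        prev_acc = None
        for donor, acceptor in self.junctions:
            if not donor < acceptor - 1:
                raise ValueError(
                    f"junction ({donor}, {acceptor}) spans an empty intron"
                )
            if prev_acc is not None and donor < prev_acc:
                raise ValueError("junctions overlap or are unsorted")
            prev_acc = acceptor

    def __len__(self) -> int:
        return len(self.junctions)

    @property
    def key(self) -> tuple[str, str]:
        return (self.chrom, self.strand)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Closed intron intervals [donor+1, acceptor-1]."""
        return tuple((d + 1, a - 1) for d, a in self.junctions)


@dataclass(frozen=True)
class TranscriptFragment:
    """One scored multi-exon transcript from one cell's input assembly."""

    id: str
    cell: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    score: float

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise ValueError(f"fragment {self.id}: needs >= 2 exons")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"fragment {self.id}: exon start > end")
            if prev_end is not None and start <= prev_end + 1:
                raise ValueError(
                    f"fragment {self.id}: exons overlap or are not separated"
                )
            prev_end = end
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"fragment {self.id}: score outside [0, 1]")

    @property
    def chain(self) -> IntronChain:
        return intron_chain_of(self)


@dataclass
class CellAssembly:
    """All scored transcript fragments loaded from one cell's GTF."""

    cell: str
    fragments: list[TranscriptFragment] = field(default_factory=list)
    n_single_exon_discarded: int = 0

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(ids) != len(set(ids)):
            raise ValueError(f"cell {self.cell}: duplicate fragment ids")


@dataclass(frozen=True)
class ScoredTranscript:
    """An output transcript with a per-cell expression probability."""

    id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    probability: float

    @property
    def chain(self) -> IntronChain:
        junctions = tuple(
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
        )
        return IntronChain(self.chrom, self.strand, junctions)


@dataclass
class ScoredAssembly:
    """Final per-cell output: transcripts with expression probabilities."""

    cell: str
    transcripts: list[ScoredTranscript] = field(default_factory=list)


def intron_chain_of(fragment: TranscriptFragment) -> IntronChain:
    """Project a fragment onto its intron chain.

    Junction ``k`` has donor = ``exons[k].end`` and acceptor =
    ``exons[k+1].start``; a fragment with ``n`` exons yields ``n - 1``
    junctions.
    """
    junctions = tuple(
        (fragment.exons[k][1], fragment.exons[k + 1][0])
        for k in range(len(fragment.exons) - 1)
    )
    return IntronChain(fragment.chrom, fragment.strand, junctions)


def _parse_gtf_records(path: str | os.PathLike) -> Iterable[tuple[int, object]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feature = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(
                    f"{path}: malformed GTF at line {lineno}: {exc}"
                ) from exc
            yield lineno, feature


def _first_attr(feature, *names: str) -> str | None:
    for name in names:
        values = feature.attributes.get(name)
        if values:
            return values[0]
    return None


def read_cell_gtf(
    path: str | os.PathLike,
    cell_id: str | None = None,
    score_attribute: str = "cov",
    normalize: bool = True,
) -> CellAssembly:
    """Load one cell's scored assembly from a GTF file.

    Exon records are grouped by ``transcript_id``, merged (duplicates
    removed, overlaps rejected) and sorted. The transcript score is taken
    from *score_attribute* on the transcript record, or on any of its exon
    records as a fallback. Single-exon transcripts are counted and dropped.

    When *normalize* is true and any raw score falls outside [0, 1], scores
    are min-max normalized per cell: ``(x - min) / (max - min)`` (a single
    distinct value maps to 1.0). With *normalize* false, out-of-range
    scores raise.
    """
    if cell_id is None:
        cell_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]

    exons: dict[str, list[Exon]] = {}
    raw_scores: dict[str, float] = {}
    strands: dict[str, tuple[str, str]] = {}
    order: list[str] = []

    for lineno, feat in _parse_gtf_records(path):
        if feat.featuretype not in ("exon", "transcript"):
            continue
        tid = _first_attr(feat, "transcript_id")
        if tid is None:
            raise GtfParseError(
                f"{path}: line {lineno}: missing transcript_id attribute"
            )
        if tid not in strands:
            strands[tid] = (feat.seqid, feat.strand or ".")
            order.append(tid)
        score_text = _first_attr(feat, score_attribute)
        if score_text is not None and tid not in raw_scores:
            try:
                raw_scores[tid] = float(score_text)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-numeric "
                    f"{score_attribute}={score_text!r}"
                ) from exc
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))

    missing = [t for t in order if t in exons and t not in raw_scores]
    if missing:
        raise GtfParseError(
            f"{path}: transcripts missing score attribute "
            f"{score_attribute!r}: {missing[:5]}"
        )

    scores = _normalized_scores(
        {t: raw_scores[t] for t in order if t in exons}, normalize, path
    )

    fragments: list[TranscriptFragment] = []
    n_single = 0
    for tid in order:
        if tid not in exons:
            continue
        merged = sorted(set(exons[tid]))
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            if s2 <= e1:
                raise GtfParseError(
                    f"{path}: transcript {tid}: overlapping exon records"
                )
        if len(merged) < 2:
            n_single += 1
            continue
        chrom, strand = strands[tid]
        fragments.append(
            TranscriptFragment(
                id=tid,
                cell=cell_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(merged),
                score=scores[tid],
            )
        )
    return CellAssembly(
        cell=cell_id, fragments=fragments, n_single_exon_discarded=n_single
    )


def _normalized_scores(
    raw: dict[str, float], normalize: bool, path
) -> dict[str, float]:
    if not raw:
        return {}
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if 0.0 <= lo and hi <= 1.0:
        return dict(raw)
    if not normalize:
        raise GtfParseError(
            f"{path}: scores outside [0, 1] and normalization disabled"
        )
    if hi == lo:
        return {t: 1.0 for t in raw}
    return {t: (v - lo) / (hi - lo) for t, v in raw.items()}


def read_reference_chains(
    path: str | os.PathLike,
) -> set[IntronChain]:
    """Load the multi-exon intron chains of a reference/truth GTF.

    Single-exon entries are ignored, mirroring the matching convention.
    """
    exons: dict[str, list[Exon]] = {}
    strands: dict[str, tuple[str, str]] = {}
    for _lineno, feat in _parse_gtf_records(path):
        if feat.featuretype != "exon":
            continue
        tid = _first_attr(feat, "transcript_id")
        if tid is None:
            continue
        strands.setdefault(tid, (feat.seqid, feat.strand or "."))
        exons.setdefault(tid, []).append((feat.start, feat.end))

    chains: set[IntronChain] = set()
    for tid, ex in exons.items():
        merged = sorted(set(ex))
        if len(merged) < 2:
            continue
        chrom, strand = strands[tid]
        junctions = tuple(
            (merged[k][1], merged[k + 1][0]) for k in range(len(merged) - 1)
        )
        chains.add(IntronChain(chrom, strand, junctions))
    return chains


def _chrom_sort_key(chrom: str):
    base = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(base)) if base.isdigit() else (1, base)


def _format_attrs(**attrs: object) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_scored_gtf(assembly: ScoredAssembly, path: str | os.PathLike) -> None:
    """Write one cell's scored output as GTF.

    Each transcript carries ``transcript_id``, ``cell_id`` and
    ``beaver_score`` (the expression probability, also exposed as ``cov`` so
    outputs round-trip through :func:`read_cell_gtf`). Records are grouped
    by chromosome, then ordered by start coordinate.
    """
    for t in assembly.transcripts:
        if not 0.0 <= t.probability <= 1.0:
            raise ValueError(f"transcript {t.id}: probability outside [0, 1]")
    ordered = sorted(
        assembly.transcripts,
        key=lambda t: (_chrom_sort_key(t.chrom), t.exons[0][0], t.id),
    )
    with open(path, "w") as out:
        out.write(f"# scored assembly for cell {assembly.cell}\n")
        for t in ordered:
            score = f"{t.probability:.6f}"
            attrs = dict(
                gene_id=t.id,
                transcript_id=t.id,
                cell_id=assembly.cell,
                beaver_score=score,
                cov=score,
            )
            span = (t.exons[0][0], t.exons[-1][1])
            out.write(
                f"{t.chrom}\tbeaver\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                f"{t.strand}\t.\t{_format_attrs(**attrs)}\n"
            )
            for start, end in t.exons:
                out.write(
                    f"{t.chrom}\tbeaver\texon\t{start}\t{end}\t.\t"
                    f"{t.strand}\t.\t{_format_attrs(**attrs)}\n"
                )


def write_candidate_gtf(
    candidates: Sequence, path: str | os.PathLike
) -> None:
    """Write the merged candidate set (any objects with id/chrom/strand/
    exons and a merging score attribute ``f_score``) as a combined GTF."""
    ordered = sorted(
        candidates, key=lambda c: (_chrom_sort_key(c.chrom), c.exons[0][0], c.id)
    )
    with open(path, "w") as out:
        out.write("# candidate full-length transcripts\n")
        for c in ordered:
            attrs = dict(
                gene_id=c.id,
                transcript_id=c.id,
                merging_score=f"{c.f_score:.6f}",
            )
            span = (c.exons[0][0], c.exons[-1][1])
            out.write(
                f"{c.chrom}\tbeaver\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                f"{c.strand}\t.\t{_format_attrs(**attrs)}\n"
            )
            for start, end in c.exons:
                out.write(
                    f"{c.chrom}\tbeaver\texon\t{start}\t{end}\t.\t"
                    f"{c.strand}\t.\t{_format_attrs(**attrs)}\n"
                )
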