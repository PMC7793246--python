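"""Core genomic data models.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GTF I/O converts at the boundary (GTF is 1-based, closed). Strand is one of
``"+"``, ``"-"`` or ``"."`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "merge_intervals",
    "BIOTYPES",
]

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A non-empty genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge a list of intervals (same chrom) into disjoint sorted intervals.

    Adjacent (bookended) intervals are merged; the strand of the result is
    that of the first input interval.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge intervals across chromosomes {sorted(chroms)}")
    strand = intervals[0].strand
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[tuple[int, int]] = [(ivs[0].start, ivs[0].end)]
    for iv in ivs[1:]:
        s, e = merged[-1]
        if iv.start <= e:
            merged[-1] = (s, max(e, iv.end))
        else:
            merged.append((iv.start, iv.end))
    chrom = intervals[0].chrom
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


@dataclass
class TranscriptModel:
    """One transcript: an ordered list of exons on a single chromosome/strand.

    Exons are stored sorted by genomic start; ``first_exon``/``last_exon``
    are defined in transcription order (5'->3'), i.e. on the minus strand
    the first exon is the highest-coordinate one.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans multiple "
                f"chromosomes/strands: {sorted(chroms)}, {sorted(strands)}"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def first_exon(self) -> GenomicInterval:
        """5'-most exon in transcription order."""
        return self.exons[-1] if self.strand == "-" else self.exons[0]

    @property
    def last_exon(self) -> GenomicInterval:
        """3'-most exon in transcription order."""
        return self.exons[0] if self.strand == "-" else self.exons[-1]


@dataclass
class GeneModel:
    """A gene: its biotype and transcript/exon structure."""

    gene_id: str
    biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id} has transcripts on multiple "
                f"chromosomes/strands: {sorted(chroms)}, {sorted(strands)}"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @cached_property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @cached_property
    def exon_union(self) -> list[GenomicInterval]:
        """Minimal disjoint sorted intervals covering every exonic base."""
        return merge_intervals([e for t in self.transcripts for e in t.exons])

    @cached_property
    def distinct_exons(self) -> list[GenomicInterval]:
        """Unique (start, end) exon intervals across transcripts, sorted."""
        seen = {(e.start, e.end) for t in self.transcripts for e in t.exons}
        return [
            GenomicInterval(self.chrom, s, e, self.strand)
            for s, e in sorted(seen)
        ]

    @cached_property
    def first_exons(self) -> list[GenomicInterval]:
        """Union of per-transcript first exons (5' in transcription order)."""
        seen = {(t.first_exon.start, t.first_exon.end) for t in self.transcripts}
        return [
            GenomicInterval(self.chrom, s, e, self.strand)
            for s, e in sorted(seen)
        ]

    @cached_property
    def last_exons(self) -> list[GenomicInterval]:
        """Union of per-transcript last exons (3' in transcription order)."""
        seen = {(t.last_exon.start, t.last_exon.end) for t in self.transcripts}
        return [
            GenomicInterval(self.chrom, s, e, self.strand)
            for s, e in sorted(seen)
        ]

    def multi_isoform(self) -> bool:
        return len(self.transcripts) >= 2

    def exonic_bases(self) -> int:
        return sum(iv.length() for iv in self.exon_union)
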