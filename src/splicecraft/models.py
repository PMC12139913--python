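"""Strand-aware transcript and gene models.

Coordinates follow the GTF convention: 1-based, inclusive on both ends.
Array arithmetic elsewhere in the package converts to 0-based half-open
offsets at the point of use and converts back before anything is written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True, order=True)
class Exon:
    """A single exon interval (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"exon start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class TranscriptModel:
    """A transcript as an ordered set of exons.

    ``exons`` are stored in ascending genomic order regardless of strand.
    TSS/TES are strand-aware: on ``+`` the TSS is the first exon start and the
    TES the last exon end; on ``-`` the TSS is the last exon end and the TES
    the first exon start.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def tss(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def tes(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based inclusive) in ascending genomic order."""
        return tuple(
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exons_in_transcription_order(self) -> tuple[Exon, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def first_exon(self) -> Exon:
        """5'-most exon in transcription orientation."""
        return self.exons_in_transcription_order()[0]

    @property
    def last_exon(self) -> Exon:
        """3'-most exon in transcription orientation."""
        return self.exons_in_transcription_order()[-1]


@dataclass
class GeneModel:
    """All transcript models of one gene, on one chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.strand != self.strand or t.chrom != self.chrom:
                raise ValueError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on chrom/strand"
                )

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


def reflect_gene(gene: GeneModel, anchor: int | None = None) -> tuple[GeneModel, int]:
    """Mirror a gene about a constant and flip its strand.

    Returns the mirrored gene together with the anchor ``C`` used, so that a
    genomic position ``x`` maps to ``C - x`` and back. Used both by the
    negative-strand detection path (which normalises to a plus-strand view)
    and by the strand-symmetry tests.
    """
    lo, hi = gene.span
    if anchor is None:
        anchor = lo + hi
    flipped = "-" if gene.strand == "+" else "+"
    new_tx = []
    for t in gene.transcripts:
        exons = tuple(
            Exon(t.chrom, anchor - e.end, anchor - e.start, flipped)
            for e in t.exons
        )
        new_tx.append(
            TranscriptModel(t.transcript_id, t.gene_id, t.chrom, flipped, exons)
        )
    return GeneModel(gene.gene_id, gene.chrom, flipped, new_tx), anchor
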