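"""ORF calling and transcript<->genome coordinate projection.

Predicted coding regions from an external translation model can be ingested
as a table and are used verbatim when supplied; otherwise a simple fallback
picks the longest ATG-initiated ORF across the three forward frames (ties go
to the 5'-most start). The CDS interval includes the stop codon and is kept
in transcript coordinates (0-based, half-open, transcription orientation);
projection through the exon blocks gives strand-aware genomic segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .models import TranscriptModel

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class ORFAnnotation:
    transcript_id: str
    cds_start: int  # transcript coords, 0-based
    cds_end: int    # half-open; includes the stop codon
    cds_segments: tuple[tuple[int, int], ...]   # genomic, 1-based inclusive
    stop_segments: tuple[tuple[int, int], ...]  # genomic span of the stop codon
    stop_in_last_exon: bool

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


def map_to_genome(
    transcript: TranscriptModel, start: int, end: int
) -> list[tuple[int, int]]:
    """Project a transcript interval [start, end) onto genomic segments.

    Segments are returned in transcription order as 1-based inclusive
    intervals; their lengths sum to ``end - start``.
    """
    if not (0 <= start <= end <= transcript.exonic_length):
        raise ValueError(
            f"interval [{start}, {end}) outside transcript "
            f"{transcript.transcript_id} of length {transcript.exonic_length}"
        )
    segments: list[tuple[int, int]] = []
    offset = 0
    for exon in transcript.exons_in_transcription_order():
        n = len(exon)
        lo, hi = max(start, offset), min(end, offset + n)
        if lo < hi:
            if transcript.strand == "+":
                segments.append((exon.start + (lo - offset), exon.start + (hi - 1 - offset)))
            else:
                segments.append((exon.end - (hi - 1 - offset), exon.end - (lo - offset)))
        offset += n
    return segments


def genome_to_transcript(transcript: TranscriptModel, pos: int) -> int:
    """Inverse projection of a genomic position to a 0-based transcript offset."""
    offset = 0
    for exon in transcript.exons_in_transcription_order():
        if exon.contains(pos):
            if transcript.strand == "+":
                return offset + (pos - exon.start)
            return offset + (exon.end - pos)
        offset += len(exon)
    raise ValueError(
        f"position {pos} is not exonic in transcript {transcript.transcript_id}"
    )


def transcript_interval(
    transcript: TranscriptModel, start: int, end: int
) -> tuple[int, int] | None:
    """Transcript-coordinate interval covered by a genomic interval, if any.

    Returns the 0-based half-open interval spanned by the exonic bases of
    ``[start, end]`` (1-based inclusive), or None when no base is exonic.
    """
    offsets = []
    for exon in transcript.exons:
        lo, hi = max(start, exon.start), min(end, exon.end)
        if lo <= hi:
            offsets.append(genome_to_transcript(transcript, lo))
            offsets.append(genome_to_transcript(transcript, hi))
    if not offsets:
        return None
    return min(offsets), max(offsets) + 1


def find_orf(sequence: str, min_len: int = 30) -> tuple[int, int] | None:
    """Longest ATG-initiated, stop-terminated ORF over the forward frames.

    Returns the CDS as a 0-based half-open interval including the stop
    codon, or None when no ORF of at least ``min_len`` nt exists. Equal
    lengths are resolved in favour of the 5'-most start.
    """
    seq = sequence.upper()
    best: tuple[int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in STOP_CODONS:
                length = i + 3 - start
                if length >= min_len and (
                    best is None
                    or length > best[1] - best[0]
                    or (length == best[1] - best[0] and start < best[0])
                ):
                    best = (start, i + 3)
                start = None
    return best


def annotate_orf(
    transcript: TranscriptModel,
    sequence: str,
    *,
    predicted: tuple[int, int] | None = None,
    min_len: int = 30,
) -> ORFAnnotation | None:
    """Build an :class:`ORFAnnotation`, preferring an external prediction."""
    cds = predicted if predicted is not None else find_orf(sequence, min_len)
    if cds is None:
        return None
    s, e = cds
    if (e - s) % 3 != 0:
        raise ValueError(
            f"CDS length {e - s} of {transcript.transcript_id} not divisible by 3"
        )
    stop_segments = tuple(map_to_genome(transcript, e - 3, e))
    last = transcript.last_exon
    # classified by the 3'-most base of the stop codon (handles the rare
    # junction-spanning codon deterministically)
    final_base = stop_segments[-1][1] if transcript.strand == "+" else stop_segments[-1][0]
    return ORFAnnotation(
        transcript_id=transcript.transcript_id,
        cds_start=s,
        cds_end=e,
        cds_segments=tuple(map_to_genome(transcript, s, e)),
        stop_segments=stop_segments,
        stop_in_last_exon=last.contains(final_base),
    )


def classify_stop_location(orf: ORFAnnotation | None) -> str:
    """'Last' / 'NotLast' stop-codon location; 'n.a.' for non-coding."""
    if orf is None:
        return "n.a."
    return "Last" if orf.stop_in_last_exon else "NotLast"


def read_orf_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read external CDS predictions: transcript_id, cds_start, cds_end (TSV).

    Coordinates are 0-based half-open transcript coordinates including the
    stop codon, matching :func:`find_orf` output.
    """
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tx, s, e = line.split()[:3]
            out[tx] = (int(s), int(e))
    return out
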