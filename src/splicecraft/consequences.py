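"""Functional-consequence classification of splicing events.

For each event this module asks: does it fall inside an open reading frame,
does it contain a stop codon (and if so, is that stop in the transcript's
last exon or upstream of it), and does it overlap a Pfam domain — including
whether it touches the domain's first or last codon (a domain start / stop
alteration). Domain hits come from an external profile-HMM search and are
ingested from its whitespace-delimited per-domain table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .events import SpliceEvent
from .models import TranscriptModel
from .orf import ORFAnnotation, map_to_genome


@dataclass
class DomainHit:
    """A protein-domain hit mapped through the CDS onto the genome."""

    transcript_id: str
    domain: str
    aa_start: int  # 1-based inclusive, protein coordinates
    aa_end: int
    nt_start: int  # transcript coordinates, 0-based half-open
    nt_end: int
    segments: tuple[tuple[int, int], ...]        # genomic, 1-based inclusive
    start_codon_segments: tuple[tuple[int, int], ...]
    stop_codon_segments: tuple[tuple[int, int], ...]


@dataclass
class EventConsequence:
    event_id: str
    event_class: str
    overlaps_orf: bool
    contains_stop: bool
    stop_last_exon: bool | None
    domain_overlap: tuple[str, ...]
    alters_domain_start: bool
    alters_domain_stop: bool


def read_domtblout(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Parse a domtblout-style table into (target, domain, ali_from, ali_to).

    The target name is the protein (here: transcript) id, the query name the
    domain; alignment coordinates are 1-based amino-acid positions.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            hits.append((f[0], f[3], int(f[17]), int(f[18])))
    return hits


def attach_domains(
    raw_hits: list[tuple[str, str, int, int]],
    orfs: dict[str, ORFAnnotation],
    transcripts: dict[str, TranscriptModel],
) -> list[DomainHit]:
    """Convert protein-coordinate hits to transcript and genomic coordinates."""
    out = []
    for tx_id, domain, aa_from, aa_to in raw_hits:
        orf = orfs.get(tx_id)
        t = transcripts.get(tx_id)
        if orf is None or t is None:
            continue
        nt_start = orf.cds_start + (aa_from - 1) * 3
        nt_end = orf.cds_start + aa_to * 3
        out.append(
            DomainHit(
                transcript_id=tx_id,
                domain=domain,
                aa_start=aa_from,
                aa_end=aa_to,
                nt_start=nt_start,
                nt_end=nt_end,
                segments=tuple(map_to_genome(t, nt_start, nt_end)),
                start_codon_segments=tuple(map_to_genome(t, nt_start, nt_start + 3)),
                stop_codon_segments=tuple(map_to_genome(t, nt_end - 3, nt_end)),
            )
        )
    return out


def _overlaps(segments, start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in segments)


def classify_event_consequences(
    events: list[SpliceEvent],
    orfs: dict[str, ORFAnnotation],
    domains: list[DomainHit],
    *,
    event_ids: list[str] | None = None,
) -> list[EventConsequence]:
    """Classify each event against the ORFs and domains of its transcripts."""
    domains_by_tx: dict[str, list[DomainHit]] = {}
    for d in domains:
        domains_by_tx.setdefault(d.transcript_id, []).append(d)

    out = []
    for i, ev in enumerate(events):
        ev_id = event_ids[i] if event_ids else f"{ev.event_class}:{ev.start}-{ev.end}"
        involved = sorted(ev.including | ev.excluding)
        overlaps_orf = False
        contains_stop = False
        stop_last: bool | None = None
        hit_domains: list[str] = []
        alters_start = False
        alters_stop = False
        for tx in involved:
            orf = orfs.get(tx)
            if orf is not None:
                if _overlaps(orf.cds_segments, ev.start, ev.end):
                    overlaps_orf = True
                if _overlaps(orf.stop_segments, ev.start, ev.end):
                    contains_stop = True
                    if stop_last is None:
                        stop_last = orf.stop_in_last_exon
            for d in domains_by_tx.get(tx, []):
                if _overlaps(d.segments, ev.start, ev.end):
                    if d.domain not in hit_domains:
                        hit_domains.append(d.domain)
                    if _overlaps(d.start_codon_segments, ev.start, ev.end):
                        alters_start = True
                    if _overlaps(d.stop_codon_segments, ev.start, ev.end):
                        alters_stop = True
        out.append(
            EventConsequence(
                event_id=ev_id,
                event_class=ev.event_class,
                overlaps_orf=overlaps_orf,
                contains_stop=contains_stop,
                stop_last_exon=stop_last if contains_stop else None,
                domain_overlap=tuple(hit_domains),
                alters_domain_start=alters_start,
                alters_domain_stop=alters_stop,
            )
        )
    return out


def consequences_frame(consequences: list[EventConsequence]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "event_class": c.event_class,
                "overlaps_orf": c.overlaps_orf,
                "contains_stop": c.contains_stop,
                "stop_last_exon": c.stop_last_exon,
                "domains": ",".join(c.domain_overlap),
                "alters_domain_start": c.alters_domain_start,
                "alters_domain_stop": c.alters_domain_stop,
            }
            for c in consequences
        ]
    )
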