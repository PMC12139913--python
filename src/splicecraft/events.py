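"""Splice-event detection and annotated-GTF emission.

Six event classes are annotated per gene: alternative promoters (alt_pro),
alternative 5' donor sites (alt5), alternative 3' acceptor sites (alt3),
cassette / mutually exclusive exons (ce), retained introns (ir), and
alternative transcription end sites (alt_end). alt_pro and alt_end come from
TSS/TES clustering; the other four are read off the normalized exon-coverage
profile of each promoter group:

* alt5 — a stepwise coverage drop inside exonic territory marks a donor used
  by a subset of transcripts while others read through. Candidates inside
  valley (intron) intervals, candidates where no transcript has an *internal*
  exon boundary, and candidates coinciding (+-window) with an alternative TES
  are discarded.
* alt3 — the mirror image: a stepwise rise into an exon marks an acceptor;
  candidates in valleys or coinciding with an alternative TSS are discarded.
* ce — an internal sub-maximum peak flanked by pronounced valleys on both
  sides; the event interval is the exon span under the peak. First and last
  exons are excluded, so promoter/end variation is not re-counted here.
  Mutually exclusive exons surface as two ce events.
* ir — the union of a structural rule (an intron of one transcript contained
  in a single exon of another) and a coverage rule (a valley interval with
  non-zero mean coverage).

Negative-strand genes are reflected onto a plus-strand view, detected there,
and the results are reflected back, so the strand anti-symmetry of the donor
and acceptor definitions holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .clusters import EndCluster, PromoterCluster, cluster_tes, cluster_tss
from .models import Exon, GeneModel, TranscriptModel, reflect_gene
from .profile import CoverageProfile, build_profile

EVENT_CLASSES = ("alt_pro", "alt5", "alt3", "ce", "ir", "alt_end")
#: fixed priority order used when concatenating composite exon labels
LABEL_ORDER = {c: i for i, c in enumerate(EVENT_CLASSES)}


@dataclass(frozen=True)
class SpliceEvent:
    """A classified event. Point events have ``start == end``."""

    event_class: str
    chrom: str
    start: int
    end: int
    including: frozenset[str]
    excluding: frozenset[str]
    promoter_cluster: int | None = None

    @property
    def key(self):
        return (self.event_class, self.start, self.end, self.including, self.excluding)


@dataclass
class TranscriptSpliceAttributes:
    """Per-transcript event membership counts and fractional positions."""

    a5: int = 0
    a3: int = 0
    ce: int = 0
    i: int = 0
    a5t: int = 0
    a3t: int = 0
    cet: int = 0
    it: int = 0
    ap: float = 0.0
    ae: float = 0.0
    promoter_group: int = 0

    def as_dict(self) -> dict[str, object]:
        return {
            "promoter_group": self.promoter_group,
            "a5": self.a5, "a5t": self.a5t,
            "a3": self.a3, "a3t": self.a3t,
            "ce": self.ce, "cet": self.cet,
            "i": self.i, "it": self.it,
            "ap": round(self.ap, 6), "ae": round(self.ae, 6),
        }


# ---------------------------------------------------------------------------
# detectors (plus-strand view)
# ---------------------------------------------------------------------------

def detect_alt5(
    profile: CoverageProfile,
    transcripts: list[TranscriptModel],
    tes_exclude: frozenset[int] = frozenset(),
    window: int = 1,
) -> list[SpliceEvent]:
    """Alternative donor sites from stepwise coverage drops (plus-view)."""
    cov = profile.coverage
    events = []
    for i in range(1, len(cov)):
        if not (cov[i] < cov[i - 1]) or cov[i] <= 0 or profile.in_valley(i):
            continue
        donor = profile.pos(i - 1)
        if any(abs(donor - p) <= window for p in tes_exclude):
            continue
        including = frozenset(
            t.transcript_id
            for t in transcripts
            if any(e.end == donor for e in t.exons[:-1])  # internal boundary
        )
        excluding = frozenset(
            t.transcript_id
            for t in transcripts
            if any(e.contains(donor) and e.contains(donor + 1) for e in t.exons)
        )
        if including and excluding:
            events.append(
                SpliceEvent("alt5", transcripts[0].chrom, donor, donor,
                            including, excluding)
            )
    return events


def detect_alt3(
    profile: CoverageProfile,
    transcripts: list[TranscriptModel],
    tss_exclude: frozenset[int] = frozenset(),
    window: int = 1,
) -> list[SpliceEvent]:
    """Alternative acceptor sites from stepwise coverage rises (plus-view)."""
    cov = profile.coverage
    events = []
    for j in range(len(cov) - 1):
        if not (cov[j] < cov[j + 1]) or cov[j] <= 0 or profile.in_valley(j):
            continue
        acceptor = profile.pos(j + 1)
        if any(abs(acceptor - p) <= window for p in tss_exclude):
            continue
        including = frozenset(
            t.transcript_id
            for t in transcripts
            if any(e.start == acceptor for e in t.exons[1:])  # internal boundary
        )
        excluding = frozenset(
            t.transcript_id
            for t in transcripts
            if any(e.contains(acceptor - 1) and e.contains(acceptor) for e in t.exons)
        )
        if including and excluding:
            events.append(
                SpliceEvent("alt3", transcripts[0].chrom, acceptor, acceptor,
                            including, excluding)
            )
    return events


def detect_cassette(
    profile: CoverageProfile,
    transcripts: list[TranscriptModel],
    valley_drop: float = 0.1,
    tol: float = 1e-6,
) -> list[SpliceEvent]:
    """Cassette / mutually exclusive exons from sub-maximum internal peaks."""
    events = []
    for mid, height, ps, pe in profile.peaks:
        if height >= 1.0 - tol:
            continue
        left = [v for v in profile.valleys if v[1] < ps]
        right = [v for v in profile.valleys if v[0] > pe]
        if not left or not right:
            continue
        lv = max(left, key=lambda v: v[1])
        rv = min(right, key=lambda v: v[0])
        if profile.valley_mean(lv) >= height - valley_drop:
            continue
        if profile.valley_mean(rv) >= height - valley_drop:
            continue
        peak_lo, peak_hi = profile.pos(ps), profile.pos(pe)
        hits: list[tuple[TranscriptModel, Exon]] = [
            (t, e)
            for t in transcripts
            for e in t.exons
            if e.overlaps(peak_lo, peak_hi)
        ]
        if not hits:
            continue
        # first/last exons excluded: the exon must be internal in at least
        # one transcript carrying it
        if not any(e in t.exons[1:-1] for t, e in hits):
            continue
        lo = min(e.start for _, e in hits)
        hi = max(e.end for _, e in hits)
        including = frozenset(t.transcript_id for t, _ in hits)
        excluding = frozenset(
            t.transcript_id
            for t in transcripts
            if any(s <= lo and hi <= e for s, e in t.introns)
        )
        if excluding:
            events.append(
                SpliceEvent("ce", transcripts[0].chrom, lo, hi, including, excluding)
            )
    return events


def detect_retained_introns(
    profile: CoverageProfile, transcripts: list[TranscriptModel]
) -> list[SpliceEvent]:
    """Retained introns: structural containment union non-zero valleys."""
    found: dict[tuple[int, int], tuple[set[str], set[str]]] = {}

    def add(lo: int, hi: int) -> None:
        including = {
            t.transcript_id
            for t in transcripts
            if any(e.start <= lo and hi <= e.end for e in t.exons)
        }
        excluding = {
            t.transcript_id
            for t in transcripts
            if any(s <= lo and hi <= e for s, e in t.introns)
        }
        if including and excluding:
            prev = found.setdefault((lo, hi), (set(), set()))
            prev[0].update(including)
            prev[1].update(excluding)

    for t in transcripts:
        for lo, hi in t.introns:
            if any(
                u is not t and any(e.start <= lo and hi <= e.end for e in u.exons)
                for u in transcripts
            ):
                add(lo, hi)
    for v in profile.valleys:
        if profile.valley_mean(v) > 0:
            add(profile.pos(v[0]), profile.pos(v[1]))

    return [
        SpliceEvent("ir", transcripts[0].chrom, lo, hi,
                    frozenset(inc), frozenset(exc))
        for (lo, hi), (inc, exc) in sorted(found.items())
    ]


# ---------------------------------------------------------------------------
# gene-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    gene: GeneModel
    events: list[SpliceEvent]
    attributes: dict[str, TranscriptSpliceAttributes]
    exon_features: dict[tuple[str, Exon], str]
    promoter_clusters: list[PromoterCluster] = field(default_factory=list)
    end_clusters: list[EndCluster] = field(default_factory=list)


def _boundary_events(
    gene: GeneModel,
    pclusters: list[PromoterCluster],
    eclusters: list[EndCluster],
) -> list[SpliceEvent]:
    events: list[SpliceEvent] = []
    if len(pclusters) > 1:
        base = min(pclusters, key=lambda c: c.ap)
        for c in pclusters:
            if c is base:
                continue
            events.append(
                SpliceEvent("alt_pro", gene.chrom, c.coordinate, c.coordinate,
                            frozenset(c.members), frozenset(base.members),
                            promoter_cluster=c.cluster_id)
            )
    if len(eclusters) > 1:
        base = min(eclusters, key=lambda c: c.ae)
        for c in eclusters:
            if c is base:
                continue
            events.append(
                SpliceEvent("alt_end", gene.chrom, c.coordinate, c.coordinate,
                            frozenset(c.members), frozenset(base.members))
            )
    return events


def _detect_group(
    group: list[TranscriptModel], window: int, valley_drop: float, tol: float
) -> list[SpliceEvent]:
    """Run the four profile detectors on one (plus-view) transcript group."""
    profile = build_profile(group)
    tss = [t.exons[0].start for t in group]
    tes = [t.exons[-1].end for t in group]
    tss_exclude = frozenset(tss) if max(tss) - min(tss) > window else frozenset()
    tes_exclude = frozenset(tes) if max(tes) - min(tes) > window else frozenset()
    events = []
    events += detect_alt5(profile, group, tes_exclude, window)
    events += detect_alt3(profile, group, tss_exclude, window)
    events += detect_cassette(profile, group, valley_drop, tol)
    events += detect_retained_introns(profile, group)
    return events


def annotate_gene(
    gene: GeneModel,
    *,
    scope: str = "promoter",
    window: int = 1,
    valley_drop: float = 0.1,
    tol: float = 1e-6,
) -> GeneAnnotation:
    """Detect all event classes for one gene and derive labels/attributes.

    ``scope`` selects whether coverage profiles are built per promoter group
    (default; one group per TSS cluster) or once per gene.
    """
    if scope not in ("promoter", "gene"):
        raise ValueError(f"scope must be 'promoter' or 'gene', got {scope!r}")
    pclusters = cluster_tss(gene, window)
    eclusters = cluster_tes(gene, window)
    events = _boundary_events(gene, pclusters, eclusters)

    if scope == "promoter":
        groups = [
            ([gene.transcript(tx) for tx in c.members], c.cluster_id)
            for c in pclusters
        ]
    else:
        groups = [(list(gene.transcripts), None)]

    # normalise to a plus-strand view; reflect results back afterwards
    anchor = None
    view = gene
    if gene.strand == "-":
        view, anchor = reflect_gene(gene)
    for members, cluster_id in groups:
        if gene.strand == "-":
            vmembers = [view.transcript(t.transcript_id) for t in members]
        else:
            vmembers = members
        for ev in _detect_group(vmembers, window, valley_drop, tol):
            if anchor is not None:
                ev = replace(ev, start=anchor - ev.end, end=anchor - ev.start)
            events.append(replace(ev, promoter_cluster=cluster_id))

    attributes = _transcript_attributes(gene, pclusters, eclusters, events)
    exon_features = _exon_features(gene, events)
    return GeneAnnotation(gene, events, attributes, exon_features,
                          pclusters, eclusters)


def _transcript_attributes(
    gene: GeneModel,
    pclusters: list[PromoterCluster],
    eclusters: list[EndCluster],
    events: list[SpliceEvent],
) -> dict[str, TranscriptSpliceAttributes]:
    attrs = {t.transcript_id: TranscriptSpliceAttributes() for t in gene.transcripts}
    for c in pclusters:
        for tx in c.members:
            attrs[tx].ap = c.ap
            attrs[tx].promoter_group = c.cluster_id
    for c in eclusters:
        for tx in c.members:
            attrs[tx].ae = c.ae
    field_of = {"alt5": "a5", "alt3": "a3", "ce": "ce", "ir": "i"}
    total_of = {"alt5": "a5t", "alt3": "a3t", "ce": "cet", "ir": "it"}
    for ev in events:
        if ev.event_class not in field_of:
            continue
        in_group = ev.including | ev.excluding
        for tx in in_group:
            cur = getattr(attrs[tx], total_of[ev.event_class])
            setattr(attrs[tx], total_of[ev.event_class], cur + 1)
        for tx in ev.including:
            cur = getattr(attrs[tx], field_of[ev.event_class])
            setattr(attrs[tx], field_of[ev.event_class], cur + 1)
    return attrs


def _exon_features(
    gene: GeneModel, events: list[SpliceEvent]
) -> dict[tuple[str, Exon], str]:
    labels: dict[tuple[str, Exon], set[str]] = {}

    def mark(tx_id: str, exon: Exon, cls: str) -> None:
        labels.setdefault((tx_id, exon), set()).add(cls)

    by_id = {t.transcript_id: t for t in gene.transcripts}
    for ev in events:
        cls = ev.event_class
        if cls == "alt_pro":
            for tx in ev.including:
                mark(tx, by_id[tx].first_exon, cls)
        elif cls == "alt_end":
            for tx in ev.including:
                mark(tx, by_id[tx].last_exon, cls)
        elif cls in ("alt5", "alt3"):
            # on +, a donor is an exon end and an acceptor an exon start;
            # mirrored on -
            donor_side = (cls == "alt5") == (gene.strand == "+")
            for tx in ev.including:
                for e in by_id[tx].exons:
                    boundary = e.end if donor_side else e.start
                    if boundary == ev.start:
                        mark(tx, e, cls)
        else:  # ce / ir: positional overlap with the event interval
            for t in gene.transcripts:
                for e in t.exons:
                    if e.overlaps(ev.start, ev.end):
                        mark(t.transcript_id, e, cls)

    out = {}
    for key, parts in labels.items():
        ordered = sorted(parts, key=LABEL_ORDER.__getitem__)
        out[key] = "exon_" + "_".join(ordered)
    return out


def annotate_genome(
    genes: list[GeneModel],
    *,
    scope: str = "promoter",
    window: int = 1,
    valley_drop: float = 0.1,
    tol: float = 1e-6,
) -> list[GeneAnnotation]:
    return [
        annotate_gene(g, scope=scope, window=window, valley_drop=valley_drop, tol=tol)
        for g in genes
    ]


def annotated_gtf(annotations: list[GeneAnnotation]) -> str:
    """Render annotated GTF text with composite exon labels and attributes."""
    from .gtf import format_gtf

    exon_features: dict[tuple[str, Exon], str] = {}
    tx_attrs: dict[str, dict[str, object]] = {}
    for ann in annotations:
        exon_features.update(ann.exon_features)
        for tx, a in ann.attributes.items():
            tx_attrs[tx] = a.as_dict()
    return format_gtf(
        [a.gene for a in annotations],
        exon_features=exon_features,
        transcript_attrs=tx_attrs,
    )


def events_frame(annotations: list[GeneAnnotation]):
    """All events as a tidy DataFrame (one row per event)."""
    import pandas as pd

    rows = []
    for ann in annotations:
        for i, ev in enumerate(sorted(ann.events, key=lambda e: (e.start, e.end, e.event_class))):
            cluster = "g" if ev.promoter_cluster is None else ev.promoter_cluster
            rows.append(
                {
                    "event_id": (
                        f"{ann.gene.gene_id}:{ev.event_class}:"
                        f"{ev.start}-{ev.end}:p{cluster}"
                    ),
                    "gene_id": ann.gene.gene_id,
                    "promoter_cluster": ev.promoter_cluster,
                    "event_class": ev.event_class,
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "end": ev.end,
                    "including": ",".join(sorted(ev.including)),
                    "excluding": ",".join(sorted(ev.excluding)),
                }
            )
    return pd.DataFrame(rows)
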