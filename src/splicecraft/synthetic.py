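"""Synthetic transcriptomes with planted splicing events and usage shifts.

The generator builds gene models whose transcript structures exhibit exactly
the requested event classes, together with ground-truth labels, so that the
annotator, the differential-usage model and the consequence classifier can
all be validated without external data.

Genes are assembled in transcription space as a chain of "slots", one per
requested event class, separated by constitutive introns. Each slot splits
the promoter group's isoforms into two fixed halves: one half carries the
variant form (the short donor exon, the distal acceptor, the cassette exon,
the retained intron), the other the reference form. Multi-promoter genes
stagger their first-exon starts but share the downstream backbone, so
alternative promoters do not leak into TES clustering. Abundances follow a
Dirichlet-multinomial: per-sample within-group proportions are drawn from a
Dirichlet centred on the condition's true usage vector (concentration =
``dispersion``) and counts multinomially from a Poisson group total. This
deliberately differs from the Beta model used for inference, so recovery
tests exercise a realistic model mismatch rather than a self-fulfilling one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import cluster_tss
from .events import SpliceEvent
from .models import Exon, GeneModel, TranscriptModel
from .orf import map_to_genome, transcript_interval

CHROM = "chrSyn1"
GENE_GAP = 10_000  # minimum spacing between synthetic genes

_WITHIN_GROUP = ("alt5", "alt3", "ce", "ir")
_ALL_CLASSES = ("alt_pro", "alt5", "alt3", "ce", "ir", "alt_end")


@dataclass(frozen=True)
class SyntheticGeneSpec:
    gene_id: str
    strand: str = "+"
    n_promoters: int = 1
    isoforms_per_promoter: int = 2
    event_classes: frozenset[str] = frozenset()
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (100, 1000)
    start: int = 1
    chrom: str = CHROM

    def validate(self) -> None:
        if self.n_promoters < 1 or self.isoforms_per_promoter < 1:
            raise ValueError("n_promoters and isoforms_per_promoter must be >= 1")
        for c in self.event_classes:
            if c not in _ALL_CLASSES:
                raise ValueError(f"unknown event class {c!r}")
        if "alt_pro" in self.event_classes and self.n_promoters < 2:
            raise ValueError("alt_pro requires n_promoters >= 2")
        within = set(self.event_classes) - {"alt_pro"}
        if within and self.isoforms_per_promoter < 2:
            raise ValueError(
                f"{sorted(within)} require isoforms_per_promoter >= 2"
            )


@dataclass
class UsageTruth:
    """Ground-truth isoform usage for one transcript within its group."""

    transcript_id: str
    gene_id: str
    promoter_group: int
    mu: dict[str, float]  # condition -> true usage mean, sums to 1 per group
    log2fc: float         # log2(mu_aged / mu_young)
    differential: bool


# ---------------------------------------------------------------------------
# structural generation
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def generate_gene(
    spec: SyntheticGeneSpec, seed: int
) -> tuple[GeneModel, list[SpliceEvent]]:
    """Build a gene model plus its truth-labelled event set.

    Coordinates are 1-based inclusive; exons are non-overlapping within each
    transcript and sorted 5'->3' genomically. Fixing the seed fixes every
    coordinate.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    k = spec.isoforms_per_promoter
    half = max(1, k // 2)
    subset_a = tuple(range(half))          # variant carriers
    subset_b = tuple(range(half, k))       # reference carriers
    classes = [c for c in _WITHIN_GROUP if c in spec.event_classes]

    # --- shared backbone in transcription space (1-based) ------------------
    # segments: (kind, params...) laid down left to right
    w0 = _draw(rng, spec.exon_length_range)
    stagger = int(rng.integers(30, 61))
    first_starts = [1 + g * stagger for g in range(spec.n_promoters)]
    first_end = first_starts[-1] + w0 - 1

    segments: list[tuple] = []
    truth_raw: list[tuple] = []  # (class, start, end, subset_inc, subset_exc)
    cursor = first_end + 1

    def intron() -> None:
        nonlocal cursor
        g = _draw(rng, spec.intron_length_range)
        segments.append(("intron", cursor, g))
        cursor += g

    def exon_all(w: int | None = None) -> None:
        nonlocal cursor
        w = w if w is not None else _draw(rng, spec.exon_length_range)
        segments.append(("exon_all", cursor, w))
        cursor += w

    for cls in classes:
        intron()
        if cls == "alt5":
            w = _draw(rng, spec.exon_length_range)
            delta = int(rng.integers(10, 51))
            segments.append(("exon_var_end", cursor, w, delta))
            truth_raw.append(("alt5", cursor + w - 1, cursor + w - 1, subset_a, subset_b))
            cursor += w + delta
        elif cls == "alt3":
            w = _draw(rng, spec.exon_length_range)
            delta = int(rng.integers(10, 51))
            segments.append(("exon_var_start", cursor, delta, w))
            truth_raw.append(
                ("alt3", cursor + delta, cursor + delta, subset_a, subset_b)
            )
            cursor += delta + w
        elif cls == "ce":
            w = _draw(rng, spec.exon_length_range)
            segments.append(("exon_subset", cursor, w))
            truth_raw.append(("ce", cursor, cursor + w - 1, subset_a, subset_b))
            cursor += w
        elif cls == "ir":
            w1 = _draw(rng, spec.exon_length_range)
            g = _draw(rng, spec.intron_length_range)
            w2 = _draw(rng, spec.exon_length_range)
            segments.append(("exon_all", cursor, w1))
            segments.append(("retained_intron", cursor + w1, g))
            segments.append(("exon_all", cursor + w1 + g, w2))
            truth_raw.append(
                ("ir", cursor + w1, cursor + w1 + g - 1, subset_a, subset_b)
            )
            cursor += w1 + g + w2

    # terminal exon; alt_end extends it for the reference half
    intron()
    w_last = _draw(rng, spec.exon_length_range)
    if "alt_end" in spec.event_classes:
        delta_end = _draw(rng, spec.intron_length_range)
        segments.append(("exon_var_end", cursor, w_last, delta_end))
        prox_tes = cursor + w_last - 1
        dist_tes = prox_tes + delta_end
        cursor += w_last + delta_end
    else:
        segments.append(("exon_all", cursor, w_last))
        prox_tes = cursor + w_last - 1
        dist_tes = None
        cursor += w_last
    total = cursor - 1

    # --- materialize per-isoform exon intervals ----------------------------
    def isoform_intervals(first_start: int, idx: int) -> list[tuple[int, int]]:
        in_a = idx in subset_a
        ivals = [(first_start, first_end)]
        for seg in segments:
            kind, s = seg[0], seg[1]
            if kind == "exon_all":
                ivals.append((s, s + seg[2] - 1))
            elif kind == "exon_var_end":
                w, delta = seg[2], seg[3]
                ivals.append((s, s + w - 1) if in_a else (s, s + w + delta - 1))
            elif kind == "exon_var_start":
                delta, w = seg[2], seg[3]
                ivals.append((s + delta, s + delta + w - 1) if in_a else (s, s + delta + w - 1))
            elif kind == "exon_subset":
                if in_a:
                    ivals.append((s, s + seg[2] - 1))
            elif kind == "retained_intron":
                if in_a:
                    ivals.append((s, s + seg[2] - 1))
            # plain introns contribute nothing
        merged: list[list[int]] = []
        for a, b in ivals:
            if merged and a == merged[-1][1] + 1:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        return [(a, b) for a, b in merged]

    # --- map to genomic coordinates ----------------------------------------
    def to_genomic_point(p: int) -> int:
        if spec.strand == "+":
            return spec.start + p - 1
        return spec.start + total - p

    def to_genomic_interval(a: int, b: int) -> tuple[int, int]:
        if spec.strand == "+":
            return to_genomic_point(a), to_genomic_point(b)
        return to_genomic_point(b), to_genomic_point(a)

    transcripts: list[TranscriptModel] = []
    ids_by_group: list[list[str]] = []
    for g in range(spec.n_promoters):
        ids = []
        for i in range(k):
            tx_id = f"{spec.gene_id}.g{g}.t{i}"
            exons = tuple(
                Exon(spec.chrom, *to_genomic_interval(a, b), spec.strand)
                for a, b in isoform_intervals(first_starts[g], i)
            )
            transcripts.append(
                TranscriptModel(tx_id, spec.gene_id, spec.chrom, spec.strand, exons)
            )
            ids.append(tx_id)
        ids_by_group.append(ids)
    gene = GeneModel(spec.gene_id, spec.chrom, spec.strand, transcripts)

    # --- truth events -------------------------------------------------------
    truth: list[SpliceEvent] = []
    for g, ids in enumerate(ids_by_group):
        for cls, a, b, inc, exc in truth_raw:
            gs, ge = to_genomic_interval(a, b)
            truth.append(
                SpliceEvent(cls, spec.chrom, gs, ge,
                            frozenset(ids[i] for i in inc),
                            frozenset(ids[i] for i in exc),
                            promoter_cluster=g)
            )
    if spec.n_promoters > 1:
        base = ids_by_group[0]
        for g in range(1, spec.n_promoters):
            pos = to_genomic_point(first_starts[g])
            truth.append(
                SpliceEvent("alt_pro", spec.chrom, pos, pos,
                            frozenset(ids_by_group[g]), frozenset(base),
                            promoter_cluster=g)
            )
    if dist_tes is not None:
        pos = to_genomic_point(dist_tes)
        dist_ids = frozenset(
            ids[i] for ids in ids_by_group for i in subset_b
        )
        prox_ids = frozenset(
            ids[i] for ids in ids_by_group for i in subset_a
        )
        truth.append(
            SpliceEvent("alt_end", spec.chrom, pos, pos, dist_ids, prox_ids)
        )
    return gene, truth


def spec_grid(
    *,
    isoform_counts: tuple[int, ...] = (2, 3, 4, 6),
    strands: tuple[str, ...] = ("+", "-"),
    include_pairs: bool = True,
) -> list[SyntheticGeneSpec]:
    """All constructible single-class specs plus pairwise combinations."""
    combos: list[frozenset[str]] = [frozenset({c}) for c in _ALL_CLASSES]
    if include_pairs:
        for i, c1 in enumerate(_ALL_CLASSES):
            for c2 in _ALL_CLASSES[i + 1:]:
                combos.append(frozenset({c1, c2}))
    specs = []
    n = 0
    for combo in combos:
        for k in isoform_counts:
            for strand in strands:
                n_prom = 2 if "alt_pro" in combo else 1
                specs.append(
                    SyntheticGeneSpec(
                        gene_id=f"SYNG{n:04d}",
                        strand=strand,
                        n_promoters=n_prom,
                        isoforms_per_promoter=k,
                        event_classes=combo,
                    )
                )
                n += 1
    return specs


def generate_genome(
    specs: list[SyntheticGeneSpec], seed: int
) -> tuple[list[GeneModel], list[SpliceEvent]]:
    """Place each spec's gene on chrSyn1, non-overlapping with >=10 kb gaps."""
    rng = np.random.default_rng(seed)
    genes, truth = [], []
    offset = 1
    for spec in specs:
        gene_seed = int(rng.integers(0, 2**31 - 1))
        placed = SyntheticGeneSpec(
            **{**spec.__dict__, "start": offset}
        )
        gene, ev = generate_gene(placed, gene_seed)
        genes.append(gene)
        truth.extend(ev)
        offset = gene.span[1] + GENE_GAP
    return genes, truth


# ---------------------------------------------------------------------------
# usage truth and count simulation
# ---------------------------------------------------------------------------

def assign_usage_truth(
    genes: list[GeneModel],
    seed: int,
    *,
    diff_fraction: float = 0.5,
    effect: float = 1.5,
    flag_threshold: float = 0.5,
    conditions: tuple[str, str] = ("young", "aged"),
) -> list[UsageTruth]:
    """Draw true per-condition usage vectors per promoter group.

    A fraction of multi-isoform groups is made differential by multiplying
    one isoform's usage odds by ``2**effect`` in the second condition and
    renormalising; transcripts whose resulting |log2FC| exceeds
    ``flag_threshold`` are flagged differential.
    """
    rng = np.random.default_rng(seed)
    young, aged = conditions
    out: list[UsageTruth] = []
    for gene in genes:
        for c in cluster_tss(gene):
            m = len(c.members)
            members = sorted(c.members)
            if m == 1:
                mu_y = np.array([1.0])
                mu_a = np.array([1.0])
            else:
                mu_y = rng.dirichlet(np.full(m, 5.0))
                mu_a = mu_y.copy()
                if rng.random() < diff_fraction:
                    j = int(rng.integers(m))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    w = mu_y.copy()
                    w[j] *= 2.0 ** (sign * effect)
                    mu_a = w / w.sum()
            for i, tx in enumerate(members):
                l2 = float(np.log2(mu_a[i] / mu_y[i]))
                out.append(
                    UsageTruth(
                        transcript_id=tx,
                        gene_id=gene.gene_id,
                        promoter_group=c.cluster_id,
                        mu={young: float(mu_y[i]), aged: float(mu_a[i])},
                        log2fc=l2,
                        differential=abs(l2) > flag_threshold,
                    )
                )
    return out


def simulate_counts(
    genes: list[GeneModel],
    truth: list[UsageTruth],
    n_reps: int = 3,
    depth: int = 1000,
    dispersion: float = 50.0,
    seed: int = 0,
    conditions: tuple[str, str] = ("young", "aged"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial counts per promoter group and sample.

    Per sample, within-group proportions are Dirichlet(dispersion * mu_c) and
    counts are multinomial on a Poisson(depth) group total, so group totals
    are conserved by construction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    truth_by_tx = {t.transcript_id: t for t in truth}
    for gene in genes:
        for t in gene.transcripts:
            if t.transcript_id not in truth_by_tx:
                raise ValueError(f"usage truth missing for {t.transcript_id}")
    rng = np.random.default_rng(seed)
    samples = [f"{cond}_{r + 1}" for cond in conditions for r in range(n_reps)]
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    )
    groups: dict[tuple[str, int], list[str]] = {}
    for gene in genes:
        for c in cluster_tss(gene):
            groups[(gene.gene_id, c.cluster_id)] = sorted(c.members)

    counts = pd.DataFrame(
        0, index=[t.transcript_id for g in genes for t in g.transcripts],
        columns=samples, dtype=int,
    )
    for (_, _), members in groups.items():
        for cond in conditions:
            mu = np.array([truth_by_tx[tx].mu[cond] for tx in members])
            if abs(mu.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"usage means for group {members} in {cond} sum to {mu.sum()}"
                )
            for r in range(n_reps):
                sample = f"{cond}_{r + 1}"
                p = rng.dirichlet(dispersion * mu) if len(mu) > 1 else np.array([1.0])
                total = rng.poisson(depth)
                counts.loc[members, sample] = rng.multinomial(total, p)
    return counts, design


# ---------------------------------------------------------------------------
# protein fixtures
# ---------------------------------------------------------------------------

_SAFE = "CGT"  # background alphabet without A: the planted ATG is unique


@dataclass
class ProteinFixtures:
    sequences: dict[str, str]
    orf_truth: pd.DataFrame      # transcript_id, cds_start, cds_end, stop_location
    domain_truth: pd.DataFrame   # transcript_id, domain, aa_start, aa_end, overlaps_event
    domtblout: str = ""

    def fasta(self) -> str:
        from io import StringIO

        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        buf = StringIO()
        records = [
            SeqRecord(Seq(s), id=tx, description="")
            for tx, s in self.sequences.items()
        ]
        seqio_write(records, buf, "fasta")
        return buf.getvalue()


def generate_protein_fixtures(
    genes: list[GeneModel],
    truth_events: list[SpliceEvent],
    seed: int,
) -> ProteinFixtures:
    """Plant ORFs and domain hits with known classifications.

    Each multi-exon transcript receives a planted ORF; stop codons alternate
    between the last exon and an upstream exon. Where a transcript includes a
    ce/ir truth event inside its CDS, a domain is planted over that event
    (expected: domain overlap); otherwise the domain goes elsewhere in the
    CDS (expected: no overlap with any truth event of that transcript).
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    orf_rows, dom_rows, dom_lines = [], [], []

    events_by_tx: dict[str, list[SpliceEvent]] = {}
    for ev in truth_events:
        for tx in ev.including:
            events_by_tx.setdefault(tx, []).append(ev)

    for gene in genes:
        for t in gene.transcripts:
            L = t.exonic_length
            seq = list("".join(rng.choice(list(_SAFE), size=L)))
            tx_exons = t.exons_in_transcription_order()
            lengths = [len(e) for e in tx_exons]
            last_start = L - lengths[-1]

            want_last = bool(rng.integers(2)) or len(tx_exons) == 1
            if want_last:
                e = L  # stop codon occupies the last 3 nt of the last exon
            else:
                # stop wholly inside the penultimate (or earlier) exon
                e = None
                off = 0
                for n in lengths[:-1]:
                    if n >= 3:
                        e = off + 3 * (n // 3)
                    off += n
            if e is None or e < 33:
                sequences[t.transcript_id] = "".join(seq)
                orf_rows.append(
                    {"transcript_id": t.transcript_id, "cds_start": -1,
                     "cds_end": -1, "stop_location": "n.a."}
                )
                continue
            max_codons = e // 3
            n_codons = int(rng.integers(11, max(12, max_codons + 1)))
            n_codons = min(n_codons, max_codons)
            s = e - 3 * n_codons
            seq[s : s + 3] = list("ATG")
            codons = ["".join(rng.choice(list(_SAFE), size=3)) for _ in range(n_codons - 2)]
            seq[s + 3 : e - 3] = list("".join(codons))
            seq[e - 3 : e] = list("TAG")
            sequences[t.transcript_id] = "".join(seq)
            stop_loc = "Last" if e - 3 >= last_start else "NotLast"
            orf_rows.append(
                {"transcript_id": t.transcript_id, "cds_start": s,
                 "cds_end": e, "stop_location": stop_loc}
            )

            # --- domain plant -------------------------------------------
            plen = n_codons - 1  # coding amino acids (stop excluded)
            if plen < 6:
                continue
            target = None
            for ev in events_by_tx.get(t.transcript_id, []):
                if ev.event_class not in ("ce", "ir"):
                    continue
                ti = transcript_interval(t, ev.start, ev.end)
                if ti is None:
                    continue
                lo = max(ti[0], s + 3)
                hi = min(ti[1], e - 3)
                if hi - lo >= 3:
                    target = (ev, lo, hi)
                    break
            if target is not None:
                ev, lo, hi = target
                aa_from = (lo - s) // 3 + 1
                aa_to = min((hi - 1 - s) // 3 + 1, plen)
                overlaps = ev.event_class
            else:
                aa_from = 2
                aa_to = min(4, plen)
                overlaps = ""
            dom_rows.append(
                {"transcript_id": t.transcript_id, "domain": f"DOM_{t.transcript_id}",
                 "aa_start": aa_from, "aa_end": aa_to, "overlaps_event": overlaps}
            )
            dom_lines.append(_domtbl_line(t.transcript_id, f"DOM_{t.transcript_id}",
                                          plen, aa_from, aa_to))

    return ProteinFixtures(
        sequences=sequences,
        orf_truth=pd.DataFrame(orf_rows),
        domain_truth=pd.DataFrame(dom_rows),
        domtblout="".join(dom_lines),
    )


def _domtbl_line(target: str, query: str, tlen: int, ali_from: int, ali_to: int) -> str:
    """One hmmsearch-domtblout-style row (whitespace-delimited, 23 columns)."""
    fields = [
        target, "-", str(tlen), query, "-", str(ali_to - ali_from + 1),
        "1e-10", "50.0", "0.1", "1", "1", "1e-10", "1e-10", "49.0", "0.1",
        "1", str(ali_to - ali_from + 1), str(ali_from), str(ali_to),
        str(ali_from), str(ali_to), "0.95", "-",
    ]
    return " ".join(fields) + "\n"
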