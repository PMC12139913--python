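"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately implemented from first principles — pairwise
interval comparisons and pure-python per-base counting — without touching
the coverage-profile machinery under test.
"""

from __future__ import annotations

from fractions import Fraction

from splicecraft.models import GeneModel, TranscriptModel


def per_base_coverage(transcripts: list[TranscriptModel]) -> dict[int, float]:
    """Coverage by direct per-base membership counting (dict-based)."""
    counts: dict[int, int] = {}
    for t in transcripts:
        for e in t.exons:
            for pos in range(e.start, e.end + 1):
                counts[pos] = counts.get(pos, 0) + 1
    n = len(transcripts)
    return {pos: c / n for pos, c in counts.items()}


def _donors(t: TranscriptModel) -> list[tuple[int, tuple[int, int]]]:
    """(donor coordinate, intron) pairs, strand-aware."""
    out = []
    for exon, intron in zip(t.exons, t.introns) if t.strand == "+" else ():
        out.append((exon.end, intron))
    if t.strand == "-":
        for exon, intron in zip(t.exons[1:], t.introns):
            out.append((exon.start, intron))
    return out


def _acceptors(t: TranscriptModel) -> list[tuple[int, tuple[int, int]]]:
    out = []
    if t.strand == "+":
        for exon, intron in zip(t.exons[1:], t.introns):
            out.append((exon.start, intron))
    else:
        for exon, intron in zip(t.exons, t.introns):
            out.append((exon.end, intron))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _reads_through(t: TranscriptModel, pos: int, nxt: int) -> bool:
    return any(e.contains(pos) and e.contains(nxt) for e in t.exons)


def group_structural_events(
    group: list[TranscriptModel], window: int = 1
) -> set[tuple]:
    """alt5/alt3/ce/ir keys from pairwise structural junction comparison."""
    strand = group[0].strand
    step = 1 if strand == "+" else -1
    chrom = group[0].chrom
    events: set[tuple] = set()

    tes = [t.tes for t in group]
    tss = [t.tss for t in group]
    tes_alt = set(tes) if max(tes) - min(tes) > window else set()
    tss_alt = set(tss) if max(tss) - min(tss) > window else set()

    # --- alternative donors -------------------------------------------------
    donor_positions = sorted({p for t in group for p, _ in _donors(t)})
    for p in donor_positions:
        if any(abs(p - q) <= window for q in tes_alt):
            continue
        owners = [t for t in group if any(d == p for d, _ in _donors(t))]
        fired = False
        for a in owners:
            intron_a = next(i for d, i in _donors(a) if d == p)
            for b in group:
                if b is a or not _reads_through(b, p, p + step):
                    continue
                if any(
                    _overlap(i, intron_a) and d != p for d, i in _donors(b)
                ):
                    fired = True
        if fired:
            inc = frozenset(t.transcript_id for t in owners)
            exc = frozenset(
                t.transcript_id for t in group if _reads_through(t, p, p + step)
            )
            events.add(("alt5", p, p, inc, exc))

    # --- alternative acceptors ----------------------------------------------
    acc_positions = sorted({p for t in group for p, _ in _acceptors(t)})
    for p in acc_positions:
        if any(abs(p - q) <= window for q in tss_alt):
            continue
        owners = [t for t in group if any(a == p for a, _ in _acceptors(t))]
        fired = False
        for a in owners:
            intron_a = next(i for d, i in _acceptors(a) if d == p)
            for b in group:
                if b is a or not _reads_through(b, p, p - step):
                    continue
                if any(
                    _overlap(i, intron_a) and d != p for d, i in _acceptors(b)
                ):
                    fired = True
        if fired:
            inc = frozenset(t.transcript_id for t in owners)
            exc = frozenset(
                t.transcript_id for t in group if _reads_through(t, p, p - step)
            )
            events.add(("alt3", p, p, inc, exc))

    # --- cassette exons -----------------------------------------------------
    skipped: set[tuple[int, int]] = set()
    for a in group:
        internal = a.exons_in_transcription_order()[1:-1]
        for e in internal:
            if any(
                s <= e.start and e.end <= x
                for b in group
                if b is not a
                for s, x in b.introns
            ):
                skipped.add((e.start, e.end))
    for lo, hi in skipped:
        inc = frozenset(
            t.transcript_id for t in group if any(x.overlaps(lo, hi) for x in t.exons)
        )
        exc = frozenset(
            t.transcript_id
            for t in group
            if any(s <= lo and hi <= x for s, x in t.introns)
        )
        events.add(("ce", lo, hi, inc, exc))

    # --- retained introns: structural containment union non-zero "valleys" --
    intervals: set[tuple[int, int]] = set()
    for a in group:
        for lo, hi in a.introns:
            if any(
                b is not a and any(e.start <= lo and hi <= e.end for e in b.exons)
                for b in group
            ):
                intervals.add((lo, hi))
    cov = per_base_coverage(group)
    span_lo = min(t.span[0] for t in group)
    span_hi = max(t.span[1] for t in group)
    # maximal constant runs that are local minima with value > 0
    runs: list[tuple[int, int, float]] = []
    pos = span_lo
    while pos <= span_hi:
        v = cov.get(pos, 0.0)
        end = pos
        while end + 1 <= span_hi and cov.get(end + 1, 0.0) == v:
            end += 1
        runs.append((pos, end, v))
        pos = end + 1
    for i, (lo, hi, v) in enumerate(runs):
        if 0 < i < len(runs) - 1 and v > 0:
            if v < runs[i - 1][2] and v < runs[i + 1][2]:
                intervals.add((lo, hi))
    for lo, hi in intervals:
        inc = frozenset(
            t.transcript_id
            for t in group
            if any(e.start <= lo and hi <= e.end for e in t.exons)
        )
        exc = frozenset(
            t.transcript_id
            for t in group
            if any(s <= lo and hi <= x for s, x in t.introns)
        )
        if inc and exc:
            events.add(("ir", lo, hi, inc, exc))
    return events


def gene_structural_events(gene: GeneModel, window: int = 1) -> set[tuple]:
    """Per-promoter-group structural events for a whole gene."""
    groups: list[list[TranscriptModel]] = []
    order = sorted(
        gene.transcripts,
        key=lambda t: (-t.tss if gene.strand == "-" else t.tss, t.transcript_id),
    )
    founders: list[int] = []
    for t in order:
        for i, f in enumerate(founders):
            if abs(t.tss - f) <= window:
                groups[i].append(t)
                break
        else:
            founders.append(t.tss)
            groups.append([t])
    events: set[tuple] = set()
    for g in groups:
        events |= group_structural_events(g, window)
    return events


def hpd_bruteforce(draws, mass: float = 0.95) -> tuple[float, float]:
    """Exhaustive search over every window holding >= mass of the draws."""
    xs = sorted(float(v) for v in draws)
    n = len(xs)
    import math

    w = math.ceil(mass * n)
    if w >= n:
        return xs[0], xs[-1]
    best = None
    for i in range(n - w):
        width = xs[i + w] - xs[i]
        if best is None or width < best[0]:
            best = (width, xs[i], xs[i + w])
    return best[1], best[2]


def binomial_two_sided_exact(k_up: int, k_down: int) -> Fraction:
    """Two-sided binomial p at p=1/2 in exact rational arithmetic."""
    from math import comb

    n = k_up + k_down
    probs = [Fraction(comb(n, k), 2**n) for k in range(n + 1)]
    observed = probs[k_up]
    return sum(p for p in probs if p <= observed)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((x, Fraction(comb(r1, x) * comb(r2, c1 - x), denom)))
    observed = next(p for x, p in probs if x == a)
    return sum(p for _, p in probs if p <= observed)
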