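"""TSS / TES clustering into promoter and end groups.

Transcripts whose start (end) sites fall within +-1 nt of a cluster's
founding coordinate share that cluster. Clustering runs in transcription
order (ascending coordinate on ``+``, descending on ``-``), so the result is
invariant to the input order of transcripts. Membership is measured against
the founding coordinate, not the nearest member, which keeps the greedy rule
deterministic: e.g. start sites {100, 101, 102} give clusters {100, 101} and
{102}, because 102 lies 2 nt from the founder 100.

Each cluster carries a fractional position over the founding coordinates:
``ap`` (promoters) is 0 for the most upstream cluster in transcription and 1
for the most downstream; ``ae`` (end sites) is 0 for the most proximal end
and approaches 1 for ends closer to the gene 3' end. On the minus strand the
calculation is inverted, since a smaller genomic coordinate lies downstream
in transcription.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import GeneModel


@dataclass
class PromoterCluster:
    cluster_id: int
    coordinate: int  # founding TSS
    members: tuple[str, ...]
    ap: float


@dataclass
class EndCluster:
    cluster_id: int
    coordinate: int  # founding TES
    members: tuple[str, ...]
    ae: float


def _greedy_clusters(
    positions: list[tuple[int, str]], *, descending: bool, window: int
) -> list[tuple[int, list[str]]]:
    ordered = sorted(positions, key=lambda p: (-p[0] if descending else p[0], p[1]))
    clusters: list[tuple[int, list[str]]] = []
    for pos, tx in ordered:
        for founder, members in clusters:
            if abs(pos - founder) <= window:
                members.append(tx)
                break
        else:
            clusters.append((pos, [tx]))
    return clusters


def _fractional(founders: list[int], *, upstream_is_min: bool) -> list[float]:
    lo, hi = min(founders), max(founders)
    if lo == hi:
        return [0.0 for _ in founders]
    span = hi - lo
    if upstream_is_min:
        return [(f - lo) / span for f in founders]
    return [(hi - f) / span for f in founders]


def cluster_tss(gene: GeneModel, window: int = 1) -> list[PromoterCluster]:
    """Group transcripts into promoter clusters by TSS (+-``window`` nt)."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    minus = gene.strand == "-"
    raw = _greedy_clusters(
        [(t.tss, t.transcript_id) for t in gene.transcripts],
        descending=minus,
        window=window,
    )
    fracs = _fractional([f for f, _ in raw], upstream_is_min=not minus)
    return [
        PromoterCluster(i, founder, tuple(members), ap)
        for i, ((founder, members), ap) in enumerate(zip(raw, fracs))
    ]


def cluster_tes(gene: GeneModel, window: int = 1) -> list[EndCluster]:
    """Group transcripts into end clusters by TES (+-``window`` nt)."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    minus = gene.strand == "-"
    raw = _greedy_clusters(
        [(t.tes, t.transcript_id) for t in gene.transcripts],
        descending=minus,
        window=window,
    )
    # downstream in transcription (higher ae): larger coordinate on +, smaller on -
    fracs = _fractional([f for f, _ in raw], upstream_is_min=not minus)
    return [
        EndCluster(i, founder, tuple(members), ae)
        for i, ((founder, members), ae) in enumerate(zip(raw, fracs))
    ]


def cluster_table(genes: list[GeneModel], window: int = 1):
    """Per-transcript cluster assignment as a DataFrame.

    Columns: gene_id, transcript_id, promoter_cluster, ap, end_cluster, ae.
    """
    import pandas as pd

    rows = []
    for gene in genes:
        p_by_tx: dict[str, PromoterCluster] = {}
        for c in cluster_tss(gene, window):
            for tx in c.members:
                p_by_tx[tx] = c
        e_by_tx: dict[str, EndCluster] = {}
        for c in cluster_tes(gene, window):
            for tx in c.members:
                e_by_tx[tx] = c
        for t in gene.transcripts:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "transcript_id": t.transcript_id,
                    "promoter_cluster": p_by_tx[t.transcript_id].cluster_id,
                    "ap": p_by_tx[t.transcript_id].ap,
                    "end_cluster": e_by_tx[t.transcript_id].cluster_id,
                    "ae": e_by_tx[t.transcript_id].ae,
                }
            )
    return pd.DataFrame(rows)
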