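"""Isoform usage proportions and percent-spliced (PS) assignment.

Raw transcript abundances are grouped by promoter of origin; a group must
show at least one non-zero count in both conditions or it is dropped (and
logged). Within a retained group, each sample's counts are converted to
proportions of the group total and clipped into [0.001, 0.999] so the Beta
likelihood stays finite. A transcript's PS value is the log2 fold change of
its replicate-averaged proportion between the two conditions; every event
inherits the PS of the transcripts that include it (and, for the skipped
form, of the transcripts that exclude it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import DifferentialCall, ModelConfig, call_differential, fit_beta_model
from .events import SpliceEvent

log = logging.getLogger(__name__)

CLIP_LO, CLIP_HI = 0.001, 0.999


@dataclass
class PromoterUsageMatrix:
    gene_id: str
    promoter_cluster: int
    isoforms: list[str]
    samples: list[str]
    conditions: dict[str, str]           # sample -> condition
    proportions: pd.DataFrame            # isoforms x samples, clipped
    raw_proportions: pd.DataFrame = field(repr=False, default=None)

    def values_for(self, isoform: str, condition: str) -> np.ndarray:
        cols = [s for s in self.samples if self.conditions[s] == condition]
        return self.proportions.loc[isoform, cols].to_numpy(dtype=float)


@dataclass
class PSRecord:
    transcript_id: str
    gene_id: str
    promoter_cluster: int
    ps: float
    significant: bool
    direction: str


def build_proportions(
    abundance: pd.DataFrame,
    design: pd.DataFrame,
    clusters: pd.DataFrame,
    conditions: tuple[str, str] = ("young", "aged"),
) -> list[PromoterUsageMatrix]:
    """Group abundances by promoter, filter, normalise and clip.

    ``abundance``: transcripts x samples; ``design``: columns sample /
    condition / replicate; ``clusters``: columns gene_id / transcript_id /
    promoter_cluster (as produced by :func:`splicecraft.clusters.cluster_table`).
    """
    cond_of = dict(zip(design["sample"], design["condition"]))
    missing = [c for c in conditions if c not in set(cond_of.values())]
    if missing:
        raise ValueError(f"conditions missing from design: {missing}")
    unknown = set(abundance.index) - set(clusters["transcript_id"])
    if unknown:
        raise ValueError(
            "transcripts absent from the transcript models: "
            + ", ".join(sorted(unknown)[:10])
        )
    samples = [s for s in abundance.columns if s in cond_of]
    matrices: list[PromoterUsageMatrix] = []
    for (gene_id, pcluster), sub in clusters.groupby(["gene_id", "promoter_cluster"]):
        isoforms = sorted(set(sub["transcript_id"]) & set(abundance.index))
        if not isoforms:
            continue
        counts = abundance.loc[isoforms, samples].astype(float)
        ok = True
        for cond in conditions:
            cols = [s for s in samples if cond_of[s] == cond]
            if counts[cols].to_numpy().sum() <= 0:
                log.info(
                    "group %s/p%s dropped: no non-zero count in %s",
                    gene_id, pcluster, cond,
                )
                ok = False
        if not ok:
            continue
        totals = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = counts.div(totals, axis=1)
        clipped = props.clip(CLIP_LO, CLIP_HI)
        matrices.append(
            PromoterUsageMatrix(
                gene_id=gene_id,
                promoter_cluster=int(pcluster),
                isoforms=isoforms,
                samples=samples,
                conditions={s: cond_of[s] for s in samples},
                proportions=clipped,
                raw_proportions=props,
            )
        )
    return matrices


def fit_usage_model(
    matrices: list[PromoterUsageMatrix],
    cfg: ModelConfig | None = None,
    conditions: tuple[str, str] = ("young", "aged"),
) -> dict[str, DifferentialCall]:
    """Fit the Beta model and apply the HPD decision rule for every isoform.

    All isoform x condition units across all groups are fitted in a single
    vectorised sampler run (the units are independent, so this changes
    nothing statistically and keeps genome-scale runs fast).
    """
    from .bayes import BetaPosterior, fit_beta_units

    cfg = cfg or ModelConfig()
    units: list[tuple[str, str]] = []
    data = []
    for m in matrices:
        for iso in m.isoforms:
            for cond in conditions:
                units.append((iso, cond))
                data.append(m.values_for(iso, cond))
    if not units:
        return {}
    alpha, beta, ra, rb = fit_beta_units(data, cfg)
    posteriors = [
        BetaPosterior(iso, cond, alpha[u], beta[u], float(ra[u]), float(rb[u]))
        for u, (iso, cond) in enumerate(units)
    ]
    return {
        c.isoform: c for c in call_differential(posteriors, cfg, conditions)
    }


def assign_ps(
    matrices: list[PromoterUsageMatrix],
    calls: dict[str, DifferentialCall],
    conditions: tuple[str, str] = ("young", "aged"),
) -> list[PSRecord]:
    """PS = log2 fold change of replicate-mean clipped proportions."""
    young, aged = conditions
    out = []
    for m in matrices:
        for iso in m.isoforms:
            mean_y = float(np.nanmean(m.values_for(iso, young)))
            mean_a = float(np.nanmean(m.values_for(iso, aged)))
            ps = float(np.log2(mean_a / mean_y))
            call = calls.get(iso)
            out.append(
                PSRecord(
                    transcript_id=iso,
                    gene_id=m.gene_id,
                    promoter_cluster=m.promoter_cluster,
                    ps=ps,
                    significant=bool(call.significant) if call else False,
                    direction=call.direction if call else "none",
                )
            )
    return out


def propagate_ps_to_events(
    ps_records: list[PSRecord],
    events: list[SpliceEvent],
    event_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (event, side, transcript) with inherited PS and call.

    Inclusion rows carry the PS of each including transcript; exclusion rows
    that of each excluding transcript. Events referencing transcripts with
    no PS record raise.
    """
    by_tx = {r.transcript_id: r for r in ps_records}
    rows = []
    for i, ev in enumerate(events):
        ev_id = (
            event_ids[i] if event_ids
            else f"ev{i}:{ev.event_class}:{ev.start}-{ev.end}"
        )
        for side, txs in (("inclusion", ev.including), ("exclusion", ev.excluding)):
            for tx in sorted(txs):
                if tx not in by_tx:
                    raise ValueError(f"event {ev_id} references unknown transcript {tx}")
                r = by_tx[tx]
                rows.append(
                    {
                        "event_id": ev_id,
                        "event_class": ev.event_class,
                        "side": side,
                        "transcript_id": tx,
                        "gene_id": r.gene_id,
                        "ps": r.ps,
                        "significant": r.significant,
                        "direction": r.direction,
                    }
                )
    return pd.DataFrame(rows)
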