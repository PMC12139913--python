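"""Affected-vs-unaffected enrichment reports.

Events inherit significance from their transcripts; the unaffected events
form an internal baseline that fixes the background frequency of each event
class, so enrichment or depletion can be quantified as odds ratios against
that baseline rather than against an external annotation. Four report
families are produced:

* up/down/unaffected tallies per event class and side with exact binomial
  tests on the up-down imbalance;
* proximal vs distal TSS/TES usage in affected vs unaffected isoforms
  (Fisher, Bonferroni-corrected) — an isoform is proximal when its cluster's
  fractional position is < 0.5;
* single- vs multi-transcript promoter counts, affected vs unaffected
  (Yates chi-square plus Fisher);
* event-class composition of affected vs unaffected sets for consequence
  strata (ORF overlap, stop-codon location, domain overlap/start/stop):
  r x c Pearson chi-square plus one-vs-rest Fisher per class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import (
    Table2x2,
    binomial_two_sided,
    bonferroni,
    chi2_2x2_yates,
    chi2_rxc,
    fisher_2x2,
)

log = logging.getLogger(__name__)

PROXIMAL_CUT = 0.5


def updown_by_class(event_ps: pd.DataFrame) -> pd.DataFrame:
    """Up/down/unaffected counts per event class and side, with binomial p.

    ``event_ps`` is the table from
    :func:`splicecraft.usage.propagate_ps_to_events`.
    """
    rows = []
    for (cls, side), sub in event_ps.groupby(["event_class", "side"]):
        sig = sub[sub["significant"]]
        up = int((sig["ps"] > 0).sum())
        down = int((sig["ps"] < 0).sum())
        unaffected = int(len(sub) - len(sig))
        p = binomial_two_sided(up, down).p if up + down > 0 else float("nan")
        rows.append(
            {"event_class": cls, "side": side, "up": up, "down": down,
             "unaffected": unaffected, "binomial_p": p}
        )
    return pd.DataFrame(rows)


def boundary_usage(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Proximal/distal TSS and TES usage, affected vs unaffected isoforms.

    ``transcripts`` needs columns transcript_id, ap, ae, significant, and
    (for direction-stratified rows) ps. Each boundary is tested with Fisher
    on a 2x2 (affected/unaffected x proximal/distal); p-values are
    Bonferroni-corrected over the rows emitted. Odds ratios are the odds of
    proximal usage in affected relative to unaffected isoforms.
    """
    rows = []
    strata = [
        ("ps_up", transcripts[transcripts["significant"] & (transcripts["ps"] > 0)]),
        ("ps_down", transcripts[transcripts["significant"] & (transcripts["ps"] < 0)]),
    ]
    unaff = transcripts[~transcripts["significant"]]
    for boundary, frac_col in (("TSS", "ap"), ("TES", "ae")):
        for name, aff in strata:
            t = Table2x2(
                int((aff[frac_col] < PROXIMAL_CUT).sum()),
                int((aff[frac_col] >= PROXIMAL_CUT).sum()),
                int((unaff[frac_col] < PROXIMAL_CUT).sum()),
                int((unaff[frac_col] >= PROXIMAL_CUT).sum()),
            )
            try:
                res = fisher_2x2(t)
                odds, p = res.odds_ratio, res.p
            except ValueError:
                odds, p = float("nan"), float("nan")
            rows.append(
                {"boundary": boundary, "stratum": name,
                 "affected_proximal": t.a, "affected_distal": t.b,
                 "unaffected_proximal": t.c, "unaffected_distal": t.d,
                 "odds_ratio": odds, "p": p}
            )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].fillna(1.0), len(out))
    return out


def promoter_complexity(
    transcripts: pd.DataFrame, clusters: pd.DataFrame
) -> pd.DataFrame:
    """Single- vs multi-transcript promoters at affected vs unaffected loci.

    A promoter group is affected when any of its transcripts is significant.
    Returns one row with the 2x2 counts, Yates chi-square and Fisher OR (odds
    of being single-transcript, affected relative to unaffected).
    """
    sig_of = dict(zip(transcripts["transcript_id"], transcripts["significant"]))
    rows = []
    for (_, _), sub in clusters.groupby(["gene_id", "promoter_cluster"]):
        txs = list(sub["transcript_id"])
        rows.append(
            {
                "affected": any(sig_of.get(tx, False) for tx in txs),
                "multi": len(txs) > 1,
            }
        )
    df = pd.DataFrame(rows)
    t = Table2x2(
        int((df["affected"] & ~df["multi"]).sum()),
        int((df["affected"] & df["multi"]).sum()),
        int((~df["affected"] & ~df["multi"]).sum()),
        int((~df["affected"] & df["multi"]).sum()),
    )
    chi = chi2_2x2_yates(t)
    fis = fisher_2x2(t)
    return pd.DataFrame(
        [
            {"affected_single": t.a, "affected_multi": t.b,
             "unaffected_single": t.c, "unaffected_multi": t.d,
             "chi2": chi.statistic, "chi2_df": chi.df, "chi2_p": chi.p,
             "odds_ratio": fis.odds_ratio, "fisher_p": fis.p}
        ]
    )


def class_composition(
    event_ps: pd.DataFrame,
    mask: pd.Series | None = None,
    *,
    classes: tuple[str, ...] = ("ce", "alt_end", "alt3", "alt5", "ir"),
) -> dict[str, object]:
    """Event-class composition of affected vs unaffected events.

    ``mask`` optionally restricts the events considered (e.g. events
    overlapping an ORF). One affected/unaffected count vector each, an r x c
    Pearson chi-square on the 2 x k table, and one-vs-rest Fisher tests per
    class. Classes absent from the data are reported with zero counts but
    dropped from the chi-square (with a warning).
    """
    df = event_ps if mask is None else event_ps[mask]
    # event-level view: an event is affected when any of its transcripts is
    events = df.groupby("event_id").agg(
        event_class=("event_class", "first"), significant=("significant", "any")
    )
    aff = events[events["significant"]]
    unaff = events[~events["significant"]]
    counts = pd.DataFrame(
        {
            "affected": [int((aff["event_class"] == c).sum()) for c in classes],
            "unaffected": [int((unaff["event_class"] == c).sum()) for c in classes],
        },
        index=list(classes),
    )
    used = counts[(counts.sum(axis=1) > 0)]
    dropped = set(classes) - set(used.index)
    if dropped:
        log.warning("classes with zero counts excluded from chi-square: %s",
                    sorted(dropped))
    chi = None
    if len(used) >= 2 and used.to_numpy().sum() > 0 and (used.sum(axis=0) > 0).all():
        chi = chi2_rxc(used.to_numpy().T)
    fisher_rows = []
    for c in classes:
        t = Table2x2(
            int(counts.loc[c, "affected"]),
            int(counts["affected"].sum() - counts.loc[c, "affected"]),
            int(counts.loc[c, "unaffected"]),
            int(counts["unaffected"].sum() - counts.loc[c, "unaffected"]),
        )
        try:
            res = fisher_2x2(t)
            fisher_rows.append(
                {"event_class": c, "odds_ratio": res.odds_ratio, "p": res.p}
            )
        except ValueError:
            fisher_rows.append(
                {"event_class": c, "odds_ratio": float("nan"), "p": float("nan")}
            )
    return {
        "counts": counts,
        "chi2": chi,
        "fisher": pd.DataFrame(fisher_rows),
    }


def affected_vs_unaffected_report(
    event_ps: pd.DataFrame,
    transcripts: pd.DataFrame | None = None,
    clusters: pd.DataFrame | None = None,
    consequences: pd.DataFrame | None = None,
) -> dict[str, object]:
    """Assemble the full report for one comparison.

    Returns a dict of DataFrames / composition dicts; sections whose inputs
    were not supplied are omitted.
    """
    report: dict[str, object] = {"updown": updown_by_class(event_ps)}
    if transcripts is not None:
        report["boundaries"] = boundary_usage(transcripts)
        if clusters is not None:
            report["promoter_complexity"] = promoter_complexity(transcripts, clusters)
    if consequences is not None:
        merged = event_ps.merge(
            consequences, on="event_id", how="left", suffixes=("", "_cons")
        )
        report["orf_overlap"] = class_composition(
            merged, merged["overlaps_orf"].fillna(False).astype(bool)
        )
        report["stop_codon"] = class_composition(
            merged, merged["contains_stop"].fillna(False).astype(bool)
        )
        report["domain_overlap"] = class_composition(
            merged, merged["domains"].fillna("").astype(str) != ""
        )
    return report
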