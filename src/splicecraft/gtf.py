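"""Reading and writing GTF transcript models.

The input is a FLAIR-collapse-style GTF: ``exon`` features carrying
``gene_id`` and ``transcript_id`` attributes, optionally accompanied by
``transcript`` rows. The annotated output of this package re-uses the exon
feature column for composite event labels (``exon_alt3_ce`` etc.), so the
reader accepts any feature that is ``exon`` or starts with ``exon_``.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

from .models import Exon, GeneModel, TranscriptModel

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into :class:`GeneModel` objects grouped by ``gene_id``.

    Exons are re-sorted in ascending genomic order. Transcripts that have no
    exon feature at all (e.g. a bare ``transcript`` row) are dropped with a
    warning. Malformed coordinates or missing mandatory attributes raise
    :class:`GtfParseError` naming the offending line.
    """
    exons_by_tx: dict[str, list[Exon]] = {}
    meta_by_tx: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    seen_tx_rows: set[str] = set()
    tx_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: malformed coordinates {start_s!r}/{end_s!r}"
                ) from None
            attrs = _parse_attributes(attrs_s)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: missing mandatory gene_id/transcript_id attribute"
                )
            tx = attrs["transcript_id"]
            if tx not in meta_by_tx:
                meta_by_tx[tx] = (attrs["gene_id"], chrom, strand)
                tx_order.append(tx)
            if feature == "transcript":
                seen_tx_rows.add(tx)
            elif feature == "exon" or feature.startswith("exon_"):
                exons_by_tx.setdefault(tx, []).append(Exon(chrom, start, end, strand))

    genes: dict[str, GeneModel] = {}
    for tx in tx_order:
        gene_id, chrom, strand = meta_by_tx[tx]
        if tx not in exons_by_tx:
            log.warning("transcript %s has no exon features; dropped", tx)
            continue
        model = TranscriptModel(tx, gene_id, chrom, strand, tuple(exons_by_tx[tx]))
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, chrom, strand, [])
        gene = genes[gene_id]
        if gene.strand != strand or gene.chrom != chrom:
            raise GtfParseError(
                f"transcript {tx} disagrees with gene {gene_id} on chrom/strand"
            )
        gene.transcripts.append(model)
    return list(genes.values())


def format_gtf(
    genes: Iterable[GeneModel],
    *,
    source: str = "splicecraft",
    exon_features: dict[tuple[str, Exon], str] | None = None,
    transcript_attrs: dict[str, dict[str, object]] | None = None,
) -> str:
    """Render gene models as GTF text.

    ``exon_features`` optionally maps ``(transcript_id, exon)`` to a composite
    feature label; ``transcript_attrs`` maps transcript ids to extra
    attributes appended to the transcript row.
    """
    out: list[str] = []
    for gene in genes:
        for t in gene.transcripts:
            base = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
            extra = ""
            if transcript_attrs and t.transcript_id in transcript_attrs:
                parts = []
                for k, v in transcript_attrs[t.transcript_id].items():
                    if isinstance(v, float):
                        parts.append(f'{k} "{v:.6g}";')
                    else:
                        parts.append(f'{k} "{v}";')
                extra = " " + " ".join(parts)
            lo, hi = t.span
            out.append(
                "\t".join(
                    [gene.chrom, source, "transcript", str(lo), str(hi), ".",
                     t.strand, ".", base + extra]
                )
            )
            for e in t.exons:
                feat = "exon"
                if exon_features is not None:
                    feat = exon_features.get((t.transcript_id, e), "exon")
                out.append(
                    "\t".join(
                        [gene.chrom, source, feat, str(e.start), str(e.end), ".",
                         t.strand, ".", base]
                    )
                )
    return "\n".join(out) + "\n"


def write_gtf(genes: Iterable[GeneModel], path: str | Path, **kwargs) -> None:
    Path(path).write_text(format_gtf(genes, **kwargs))
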