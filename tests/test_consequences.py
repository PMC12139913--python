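"""ORF calling, coordinate projection, and consequence classification."""

import numpy as np
import pytest

from splicecraft.consequences import (
    attach_domains,
    classify_event_consequences,
    read_domtblout,
)
from splicecraft.events import SpliceEvent, annotate_gene
from splicecraft.models import Exon, TranscriptModel
from splicecraft.orf import (
    annotate_orf,
    classify_stop_location,
    find_orf,
    genome_to_transcript,
    map_to_genome,
    transcript_interval,
)
from splicecraft.synthetic import (
    generate_genome,
    generate_protein_fixtures,
    spec_grid,
)


def _tx(tid, blocks, strand="+"):
    return TranscriptModel(
        tid, "g", "chr1", strand,
        tuple(Exon("chr1", a, b, strand) for a, b in blocks),
    )


class TestFindOrf:
    def test_embedded_orf_found(self):
        seq = "CCCCC" + "ATG" + "AAA" * 9 + "TAG" + "CCCCC"
        cds = find_orf(seq)
        assert cds == (5, 5 + 33)
        assert seq[cds[1] - 3 : cds[1]] == "TAG"

    def test_short_orfs_flagged_noncoding(self):
        assert find_orf("CCATGAAATAGCC") is None  # 9 nt < 30
        assert find_orf("CCCCCCCCC") is None

    def test_tie_goes_to_five_prime_most(self):
        orf = "ATG" + "CCC" * 9 + "TAG"
        seq = orf + "T" + orf  # same length, different frames
        assert find_orf(seq) == (0, len(orf))

    def test_longest_wins_across_frames(self):
        short = "ATG" + "CCC" * 9 + "TAG"
        long = "ATG" + "GGG" * 20 + "TAA"
        seq = short + "TT" + long
        assert find_orf(seq) == (len(short) + 2, len(short) + 2 + len(long))


class TestProjection:
    def test_single_exon_interval(self):
        t = _tx("t", [(100, 199), (300, 399)])
        assert map_to_genome(t, 10, 20) == [(110, 119)]

    def test_interval_spanning_intron(self):
        t = _tx("t", [(100, 199), (300, 399)])
        segs = map_to_genome(t, 90, 110)
        assert segs == [(190, 199), (300, 309)]
        assert sum(e - s + 1 for s, e in segs) == 20

    def test_minus_strand_projection(self):
        t = _tx("t", [(100, 199), (300, 399)], strand="-")
        # transcript starts at genomic 399 and runs leftwards
        assert map_to_genome(t, 0, 10) == [(390, 399)]
        segs = map_to_genome(t, 95, 105)
        assert segs == [(300, 304), (195, 199)]

    def test_out_of_range_rejected(self):
        t = _tx("t", [(100, 199)])
        with pytest.raises(ValueError, match="outside transcript"):
            map_to_genome(t, 0, 500)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_projection_inverse_roundtrip(self, strand):
        rng = np.random.default_rng(0)
        t = _tx("t", [(100, 180), (300, 420), (600, 650)], strand=strand)
        L = t.exonic_length
        for _ in range(50):
            a = int(rng.integers(0, L))
            b = int(rng.integers(a + 1, L + 1))
            segs = map_to_genome(t, a, b)
            assert sum(e - s + 1 for s, e in segs) == b - a
            back = sorted(
                genome_to_transcript(t, p)
                for s, e in segs
                for p in (s, e)
            )
            assert back[0] == a and back[-1] == b - 1
            lo, hi = transcript_interval(t, min(s for s, _ in segs),
                                         max(e for _, e in segs))
            assert (lo, hi) == (a, b)


class TestStopLocation:
    def test_stop_in_final_exon_is_last(self):
        t = _tx("t", [(100, 199), (300, 399)])
        seq = "C" * 130 + "ATG" + "CCC" * 20 + "TAG" + "C" * 4
        orf = annotate_orf(t, seq)
        assert orf.stop_in_last_exon
        assert classify_stop_location(orf) == "Last"

    def test_upstream_stop_is_not_last(self):
        t = _tx("t", [(100, 199), (300, 399), (500, 599)])
        seq = "C" * 10 + "ATG" + "CCC" * 20 + "TAG" + "C" * 225
        orf = annotate_orf(t, seq)  # stop ends at offset 85, exon 1
        assert not orf.stop_in_last_exon
        assert classify_stop_location(orf) == "NotLast"

    def test_noncoding_is_na(self):
        assert classify_stop_location(None) == "n.a."


class TestEventConsequences:
    def _setup_gene(self):
        # long isoform with cassette exon, short isoform skips it
        long = _tx("long", [(100, 199), (300, 399), (500, 599)])
        short = _tx("short", [(100, 199), (500, 599)])
        ce = SpliceEvent("ce", "chr1", 300, 399,
                         frozenset({"long"}), frozenset({"short"}))
        return long, short, ce

    def test_domain_in_skipped_exon_flagged(self):
        long, short, ce = self._setup_gene()
        # CDS covers all three exons; domain codons sit inside the middle exon
        seq = "C" * 30 + "ATG" + "CCC" * 80 + "TAG" + "C" * 24
        orfs = {"long": annotate_orf(long, seq)}
        hits = attach_domains([("long", "NDUS4", 31, 40)], orfs,
                              {"long": long})
        (cons,) = classify_event_consequences([ce], orfs, hits)
        assert cons.overlaps_orf
        assert cons.domain_overlap == ("NDUS4",)
        # short isoform has no domain hit at all: domain lost by skipping
        assert all(h.transcript_id == "long" for h in hits)

    def test_central_domain_codons_no_start_stop_alteration(self):
        long, short, ce = self._setup_gene()
        seq = "C" * 30 + "ATG" + "CCC" * 80 + "TAG" + "C" * 24
        orfs = {"long": annotate_orf(long, seq)}
        # domain spans the whole CDS; the event only covers central codons
        hits = attach_domains([("long", "BIG", 1, 80)], orfs, {"long": long})
        (cons,) = classify_event_consequences([ce], orfs, hits)
        assert cons.domain_overlap == ("BIG",)
        assert not cons.alters_domain_start and not cons.alters_domain_stop

    def test_event_truncating_domain_end_alters_stop(self):
        long, short, ce = self._setup_gene()
        seq = "C" * 30 + "ATG" + "CCC" * 80 + "TAG" + "C" * 24
        orfs = {"long": annotate_orf(long, seq)}
        # domain's final codon lies inside the cassette exon
        # exon2 covers transcript offsets 100..199; CDS starts at 30
        hits = attach_domains([("long", "EDGE", 5, 40)], orfs, {"long": long})
        (cons,) = classify_event_consequences([ce], orfs, hits)
        assert cons.alters_domain_stop and not cons.alters_domain_start

    def test_domtblout_roundtrip(self, tmp_path):
        line = ("tx1 - 100 PF0001 - 40 1e-10 50.0 0.1 1 1 1e-10 1e-10 49.0 "
                "0.1 1 40 11 50 11 50 0.95 -\n")
        p = tmp_path / "hits.domtblout"
        p.write_text("# comment\n" + line)
        assert read_domtblout(p) == [("tx1", "PF0001", 11, 50)]


class TestFixtureRoundTrip:
    def test_planted_orfs_domains_recovered(self):
        """20+ random fixtures: recovered CDS, stop location and domain
        overlap all match the planted labels exactly."""
        genes, truth = generate_genome(
            spec_grid(isoform_counts=(2, 3), include_pairs=False), seed=61
        )
        genes = genes[:30]
        gene_ids = {g.gene_id for g in genes}
        truth = [e for e in truth
                 if next(iter(e.including)).split(".")[0] in gene_ids]
        fx = generate_protein_fixtures(genes, truth, seed=62)
        tx_by_id = {t.transcript_id: t for g in genes for t in g.transcripts}

        n_coding = 0
        orfs = {}
        for _, row in fx.orf_truth.iterrows():
            t = tx_by_id[row["transcript_id"]]
            orf = annotate_orf(t, fx.sequences[t.transcript_id])
            if row["stop_location"] == "n.a.":
                assert orf is None
                continue
            n_coding += 1
            assert (orf.cds_start, orf.cds_end) == (row["cds_start"], row["cds_end"])
            assert classify_stop_location(orf) == row["stop_location"]
            orfs[t.transcript_id] = orf
        assert n_coding >= 20

        raw = [
            (r["transcript_id"], r["domain"], r["aa_start"], r["aa_end"])
            for _, r in fx.domain_truth.iterrows()
        ]
        hits = attach_domains(raw, orfs, tx_by_id)
        events = truth
        ids = [f"ev{i}" for i in range(len(events))]
        cons = classify_event_consequences(events, orfs, hits, event_ids=ids)
        planted = {
            (r["transcript_id"], r["domain"]): r["overlaps_event"]
            for _, r in fx.domain_truth.iterrows()
        }
        # every domain planted over a ce/ir event shows up as a domain
        # overlap on an event of that class involving that transcript
        for (tx, dom), cls in planted.items():
            if not cls:
                continue
            matching = [
                c for c, ev in zip(cons, events)
                if ev.event_class == cls and tx in (ev.including | ev.excluding)
                and dom in c.domain_overlap
            ]
            assert matching, (tx, dom, cls)

    def test_fixture_fasta_and_domtblout_parse(self, tmp_path):
        genes, truth = generate_genome(
            spec_grid(isoform_counts=(2,), include_pairs=False), seed=63
        )
        fx = generate_protein_fixtures(genes[:5], truth, seed=64)
        fasta = tmp_path / "tx.fa"
        fasta.write_text(fx.fasta())
        from Bio import SeqIO

        records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        assert records == fx.sequences
        dom = tmp_path / "hits.domtblout"
        dom.write_text(fx.domtblout)
        parsed = read_domtblout(dom)
        assert len(parsed) == len(fx.domain_truth)
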