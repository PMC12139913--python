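"""Coverage profiles and splice-event detection vs structural oracles."""

import numpy as np
import pytest

from splicecraft.events import annotate_gene, annotate_genome, annotated_gtf
from splicecraft.models import Exon, GeneModel, TranscriptModel, reflect_gene
from splicecraft.profile import build_profile
from splicecraft.synthetic import SyntheticGeneSpec, generate_gene, generate_genome, spec_grid

from oracles import gene_structural_events, per_base_coverage

PROFILE_CLASSES = {"alt5", "alt3", "ce", "ir"}


def _tx(tid, blocks, strand="+", gene="G", chrom="chr1"):
    return TranscriptModel(
        tid, gene, chrom, strand,
        tuple(Exon(chrom, a, b, strand) for a, b in blocks),
    )


def _gene_of(*txs):
    return GeneModel(txs[0].gene_id, txs[0].chrom, txs[0].strand, list(txs))


class TestCoverageProfile:
    def test_single_transcript_is_exon_indicator(self):
        t = _tx("t", [(100, 150), (300, 400)])
        p = build_profile([t])
        assert p.coverage[0] == 1.0 and p.coverage[-1] == 1.0
        assert p.coverage[200 - 100] == 0.0
        assert [h for _, h, _, _ in p.peaks] == [1.0, 1.0]
        assert p.valleys == [(51, 199)]

    def test_skipped_middle_exon_half_height(self):
        a = _tx("a", [(100, 150), (300, 350), (500, 600)])
        b = _tx("b", [(100, 150), (500, 600)])
        p = build_profile([a, b])
        heights = [h for _, h, _, _ in p.peaks]
        assert heights == [1.0, 0.5, 1.0]

    def test_matches_per_base_oracle_on_random_groups(self, grid_genome):
        genes, _ = grid_genome
        for gene in genes[::11]:
            p = build_profile(list(gene.transcripts))
            oracle = per_base_coverage(list(gene.transcripts))
            for off, v in enumerate(p.coverage):
                assert v == pytest.approx(oracle.get(p.pos(off), 0.0))

    def test_coverage_conservation(self, grid_genome):
        genes, _ = grid_genome
        for gene in genes[::13]:
            p = build_profile(list(gene.transcripts))
            total = p.coverage.sum() * len(gene.transcripts)
            assert total == pytest.approx(
                sum(t.exonic_length for t in gene.transcripts)
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])


class TestDetectorConstructions:
    def test_alt5_at_shorter_donor(self):
        a = _tx("a", [(100, 200), (400, 500)])
        b = _tx("b", [(100, 210), (400, 500)])
        ann = annotate_gene(_gene_of(a, b))
        (ev,) = [e for e in ann.events if e.event_class == "alt5"]
        assert (ev.start, ev.end) == (200, 200)
        assert ev.including == {"a"} and ev.excluding == {"b"}

    def test_alt5_mirrored_on_minus_strand(self):
        a = _tx("a", [(100, 200), (400, 500)])
        b = _tx("b", [(100, 210), (400, 500)])
        gene = _gene_of(a, b)
        mirrored, anchor = reflect_gene(gene)
        ann = annotate_gene(mirrored)
        (ev,) = [e for e in ann.events if e.event_class == "alt5"]
        assert ev.start == anchor - 200
        assert ev.including == {"a"}

    def test_alt3_at_distal_acceptor(self):
        a = _tx("a", [(100, 200), (320, 400)])
        b = _tx("b", [(100, 200), (300, 400)])
        ann = annotate_gene(_gene_of(a, b))
        (ev,) = [e for e in ann.events if e.event_class == "alt3"]
        assert (ev.start, ev.end) == (320, 320)
        assert ev.including == {"a"} and ev.excluding == {"b"}

    def test_cassette_exon_and_no_event_when_constitutive(self):
        a = _tx("a", [(100, 150), (300, 350), (500, 600)])
        b = _tx("b", [(100, 150), (500, 600)])
        ann = annotate_gene(_gene_of(a, b))
        (ev,) = [e for e in ann.events if e.event_class == "ce"]
        assert (ev.start, ev.end) == (300, 350)
        constitutive = annotate_gene(
            _gene_of(a, _tx("c", [(100, 150), (300, 350), (500, 600)]))
        )
        assert [e for e in constitutive.events if e.event_class == "ce"] == []

    def test_mutually_exclusive_exons_are_two_ce_events(self):
        a = _tx("a", [(100, 150), (300, 350), (700, 800)])
        b = _tx("b", [(100, 150), (500, 550), (700, 800)])
        ann = annotate_gene(_gene_of(a, b))
        ce = sorted(
            (e.start, e.end) for e in ann.events if e.event_class == "ce"
        )
        assert ce == [(300, 350), (500, 550)]

    def test_retained_intron_and_clean_intron(self):
        a = _tx("a", [(100, 200), (400, 500)])
        b = _tx("b", [(100, 500)])
        ann = annotate_gene(_gene_of(a, b))
        (ev,) = [e for e in ann.events if e.event_class == "ir"]
        assert (ev.start, ev.end) == (201, 399)
        assert ev.including == {"b"} and ev.excluding == {"a"}
        clean = annotate_gene(
            _gene_of(a, _tx("c", [(100, 200), (400, 500)]))
        )
        assert [e for e in clean.events if e.event_class == "ir"] == []

    def test_no_events_single_promoter_single_end(self):
        a = _tx("a", [(100, 200), (400, 500)])
        b = _tx("b", [(100, 200), (400, 500)])
        ann = annotate_gene(_gene_of(a, b))
        assert ann.events == []
        for attrs in ann.attributes.values():
            assert (attrs.a5, attrs.a3, attrs.ce, attrs.i) == (0, 0, 0, 0)

    def test_donor_candidate_at_alternative_tes_discarded(self):
        # a and b form a genuine donor pair at 200 vs 250, but transcript c
        # terminates exactly at 200: the candidate coincides with an
        # alternative TES position and must be discarded
        a = _tx("a", [(100, 200), (400, 500)])
        b = _tx("b", [(100, 250), (400, 500)])
        without_c = annotate_gene(_gene_of(a, b))
        assert [
            (e.start, e.end) for e in without_c.events if e.event_class == "alt5"
        ] == [(200, 200)]
        c = _tx("c", [(100, 200)])
        with_c = annotate_gene(_gene_of(a, b, c))
        assert [e for e in with_c.events if e.event_class == "alt5"] == []
        assert any(e.event_class == "alt_end" for e in with_c.events)


class TestOracleEquivalence:
    def test_grid_round_trip_exact(self, grid_genome):
        """Annotator output equals planted truth on every constructible spec."""
        genes, truth = grid_genome
        truth_by_gene = {}
        for ev in truth:
            gid = next(iter(ev.including)).split(".")[0]
            truth_by_gene.setdefault(gid, set()).add(ev.key)
        for gene in genes:
            ann = annotate_gene(gene)
            got = {e.key for e in ann.events}
            assert got == truth_by_gene.get(gene.gene_id, set()), gene.gene_id

    def test_structural_oracle_equivalence_500_genes(self):
        """Profile-based alt5/alt3/ce/ir equals pairwise structural comparison."""
        specs = spec_grid(isoform_counts=(2, 3, 4, 5, 6))
        genes = []
        for seed in (23, 57):
            batch, _ = generate_genome(specs, seed=seed)
            genes += batch
        extra, _ = generate_genome(spec_grid(isoform_counts=(2, 6)), seed=91)
        genes += extra
        assert len(genes) >= 500
        mismatches = []
        for gene in genes:
            detected = {
                e.key for e in annotate_gene(gene).events
                if e.event_class in PROFILE_CLASSES
            }
            oracle = {
                k for k in gene_structural_events(gene) if k[0] in PROFILE_CLASSES
            }
            if detected != oracle:
                mismatches.append((gene.gene_id, detected ^ oracle))
        assert mismatches == []

    def test_strand_antisymmetry(self):
        """Mirroring a gene swaps alt5 and alt3 events at mirrored positions."""
        specs = spec_grid(isoform_counts=(2, 4), strands=("+",))
        genes, _ = generate_genome(specs, seed=99)
        for gene in genes[::5]:
            mirrored, anchor = reflect_gene(gene)
            fwd = annotate_gene(gene).events
            rev = annotate_gene(mirrored).events
            swap = {"alt5": "alt5", "alt3": "alt3"}
            fwd_keys = {
                (e.event_class, anchor - e.end, anchor - e.start,
                 e.including, e.excluding)
                for e in fwd if e.event_class in ("alt5", "alt3")
            }
            rev_keys = {
                (swap[e.event_class], e.start, e.end, e.including, e.excluding)
                for e in rev if e.event_class in ("alt5", "alt3")
            }
            assert fwd_keys == rev_keys


class TestAnnotatedGtf:
    def test_composite_label_orders_alt3_before_ce(self):
        # one isoform skips the middle exon; another shortens its acceptor
        a = _tx("a", [(100, 150), (300, 350), (500, 600)])
        b = _tx("b", [(100, 150), (500, 600)])
        c = _tx("c", [(100, 150), (320, 350), (500, 600)])
        ann = annotate_gene(_gene_of(a, b, c))
        feats = set(ann.exon_features.values())
        assert "exon_alt3_ce" in feats

    def test_truth_labels_and_attributes(self):
        spec = SyntheticGeneSpec("G1", "+", 2, 2,
                                 frozenset({"ce", "alt_end"}))
        gene, truth = generate_gene(spec, 3)
        ann = annotate_gene(gene)
        feats = set(ann.exon_features.values())
        assert {"exon_alt_pro", "exon_ce", "exon_alt_end"} <= feats
        for attrs in ann.attributes.values():
            assert attrs.ce <= attrs.cet and attrs.a5 <= attrs.a5t
        # downstream promoter members carry ap = 1
        aps = {tx: a.ap for tx, a in ann.attributes.items()}
        assert {v for v in aps.values()} == {0.0, 1.0}

    def test_byte_identical_output(self, grid_genome):
        genes, _ = grid_genome
        subset = genes[:40]
        text1 = annotated_gtf(annotate_genome(subset))
        text2 = annotated_gtf(annotate_genome(subset))
        assert text1 == text2
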