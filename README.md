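# splicecraft

Transcript-centric alternative-splicing analysis for long-read isoform
models.

Long-read (e.g. nanopore direct-RNA) sequencing yields full-length
transcript models, so alternative promoters, splice-site choices, cassette
exons, retained introns and poly(A) sites are observed jointly in each
molecule. `splicecraft` takes a collapsed isoform GTF plus a per-sample
abundance table for two conditions and

1. clusters transcription start/end sites into promoter and end groups
   (±1 nt windows, fractional positions `ap`/`ae`);
2. builds a per-group **normalized exon-coverage profile** (coverage at a
   base = fraction of transcripts whose exons contain it) and reads six
   event classes off it: alternative promoters (`alt_pro`), alternative 5′
   donors (`alt5`), alternative 3′ acceptors (`alt3`), cassette / mutually
   exclusive exons (`ce`), retained introns (`ir`) and alternative end
   sites (`alt_end`), emitting an annotated GTF with composite exon labels
   (`exon_alt3_ce`, …) and per-transcript attributes
   (`a5 a3 ce i a5t a3t cet it ap ae`);
3. fits a **Bayesian Beta model** of within-promoter isoform usage: per
   isoform and condition, clipped usage proportions x ~ Beta(α, β) with
   Gamma(5, 1) priors on α and β, sampled by adaptive random-walk
   Metropolis. An isoform is differentially used when the 95 % HPD interval
   of log₂(μ_aged/μ_young), μ = α/(α+β), excludes zero **and**
   max(P_up, 1−P_up) > 0.95;
4. assigns each transcript a **percent-spliced (PS)** value — the log₂
   fold change of its replicate-mean usage proportion — which every
   embedded event inherits (inclusion side from including transcripts,
   exclusion side from excluding ones);
5. classifies functional consequences (ORF overlap, stop codon in last vs
   upstream exon, Pfam-domain overlap and start/stop alteration) from
   ingested CDS predictions and domain-search tables (a longest-ORF
   fallback is built in); and
6. runs the **affected-vs-unaffected** enrichment battery: exact binomial
   tests on up/down counts, Fisher exact tests (cross-product OR),
   Yates-corrected 2×2 and plain Pearson r×c chi-squares, Bonferroni
   correction.

A first-class synthetic-transcriptome module generates gene models with
planted events, Dirichlet-multinomial counts with known usage shifts, and
protein fixtures with planted ORFs/domains, so the whole pipeline is
testable without downloads.

## Worked example

```python
from splicecraft import (SyntheticGeneSpec, generate_gene, annotate_gene,
                         Table2x2, chi2_2x2_yates, fisher_2x2,
                         binomial_two_sided)

spec = SyntheticGeneSpec("DEMO", strand="+", n_promoters=1,
                         isoforms_per_promoter=2,
                         event_classes=frozenset({"ce", "ir"}))
gene, truth = generate_gene(spec, seed=42)
ann = annotate_gene(gene)
for ev in sorted(ann.events, key=lambda e: e.start):
    print(f"{ev.event_class:4s} {ev.chrom}:{ev.start}-{ev.end} "
          f"in={sorted(ev.including)} ex={sorted(ev.excluding)}")
for tx, a in ann.attributes.items():
    print(tx, a.as_dict())
```

prints

```
ce   chrSyn1:789-964 in=['DEMO.g0.t0'] ex=['DEMO.g0.t1']
ir   chrSyn1:1724-1900 in=['DEMO.g0.t0'] ex=['DEMO.g0.t1']
DEMO.g0.t0 {'promoter_group': 0, 'a5': 0, 'a5t': 0, 'a3': 0, 'a3t': 0, 'ce': 1, 'cet': 1, 'i': 1, 'it': 1, 'ap': 0.0, 'ae': 0.0}
DEMO.g0.t1 {'promoter_group': 0, 'a5': 0, 'a5t': 0, 'a3': 0, 'a3t': 0, 'ce': 0, 'cet': 1, 'i': 0, 'it': 1, 'ap': 0.0, 'ae': 0.0}
```

— isoform t0 carries a cassette exon and a retained intron that isoform t1
splices out; both transcripts sit in one promoter group (`ap = 0`), and the
totals (`cet`, `it`) say one event of each class exists in the group.

The statistics module works on plain count tables. For example, 2237
single- vs 1305 multi-transcript promoters at age-biased loci against
3196 vs 1405 at age-neutral loci:

```python
t = Table2x2(2237, 1305, 3196, 1405)
print(f"chi2 = {chi2_2x2_yates(t).statistic:.2f}")          # chi2 = 35.57
print(f"OR = {fisher_2x2(t).odds_ratio:.3f}, "
      f"p = {fisher_2x2(t).p:.3g}")                          # OR = 0.754, p = 2.57e-09
print(f"binomial p (86 up / 26 down) = "
      f"{binomial_two_sided(86, 26).p:.2g}")                 # 1.1e-08
```

The multi-transcript odds are ~1.33× higher at age-biased loci (1/OR), and
an 86-up / 26-down event imbalance is wildly non-random.

## Command line

```bash
splicecraft simulate  --out-dir sim --seed 5          # synthetic study
splicecraft annotate  --gtf sim/transcripts.gtf --out annotated.gtf \
                      --events events.tsv --profile-scope promoter
splicecraft diffusage --counts sim/counts.tsv --design sim/design.tsv \
                      --clusters sim/clusters.tsv --out calls.tsv \
                      --chains 4 --draws 5000 --seed 1337
splicecraft report    --events events_ps.tsv --out report.tsv
```

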