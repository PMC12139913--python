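# Methods

## Scope and model of the data

`splicecraft` analyses collapsed long-read transcript models (a
FLAIR-collapse-style GTF) together with a per-sample transcript abundance
table for two conditions with replicates. The unit of analysis is the
full-length transcript: because a long read spans the whole mRNA, every
splicing choice a molecule makes is observed jointly, so events are scored
through whole-isoform usage proportions rather than through junction reads.
Upstream steps (alignment, splice correction, isoform collapsing,
quantification, external ORF prediction, profile-HMM domain search) are out
of scope; their outputs are inputs here.

## Promoter and end-site clustering

Transcripts of a gene are grouped by transcription start site: a TSS joins
the first existing cluster whose *founding* coordinate lies within ±1 nt,
else it founds a new cluster. Processing runs in transcription order
(ascending coordinate on `+`, descending on `-`), which makes the result
independent of input order; measuring against the founder rather than the
nearest member keeps the greedy rule deterministic (start sites
{100, 101, 102} give {100, 101} and {102}). The same procedure applied to
strand-aware transcript end sites yields end clusters. Each cluster carries
a fractional position over the founding coordinates — `ap` = 0 for the most
upstream promoter and 1 for the most downstream, `ae` analogously for end
sites with the inversion on the minus strand (a smaller genomic coordinate
is downstream in transcription there). A gene with a single cluster gets 0.

The ±1 nt window, the founder rule and the transcription-order processing
are design choices; the window is configurable (`window=`).

## Normalized exon-coverage profile

For each promoter group (or whole gene, `scope="gene"`), all exons are
superimposed on the axis from the group's first exon start to its last exon
end. Coverage at a base is the fraction of group transcripts whose exons
contain it: 1.0 where all agree, fractional where a subset does, 0 in
shared introns. Because transcript models are interval sets the profile is
piecewise constant, so peaks and valleys are plateaus: a maximal
equal-coverage run that exceeds both neighbours is a peak (represented at
its midpoint, left-biased for even lengths), one below both neighbours is a
valley — the expanded intron span between flanking exons.

The denominator is the group size, making coverage an inclusion fraction;
this is the reading under which shared bases sit at ~1.0 and subset bases
below 1.0.

## Event detection

Six classes are annotated. Minus-strand genes are reflected onto a
plus-strand view, detected there, and reflected back, so donor/acceptor
strand symmetry holds by construction.

* **alt_pro** — every promoter cluster other than the most upstream one;
  the event's transcripts are the cluster members, the baseline cluster's
  members are the excluding side.
* **alt5** (alternative donor) — a stepwise coverage drop inside exonic
  territory: position *i* with coverage below position *i−1*. Candidates
  inside valley intervals are intron boundaries, not donors, and are
  discarded; so are candidates within the clustering window of an
  alternative TES (termination, not splicing), and candidates where no
  transcript has an *internal* exon boundary at the coordinate. Including
  transcripts end an internal exon at the donor; excluding transcripts read
  through it.
* **alt3** (alternative acceptor) — the mirror image: a stepwise rise into
  an exon, skipping intronic positions and candidates at alternative
  promoter positions.
* **ce** (cassette / mutually exclusive exons) — an internal sub-maximum
  peak (height < 1 − 1e-6) flanked on both sides by pronounced valleys
  (valley coverage < peak height − 0.1, configurable `valley_drop`); the
  event interval is the exon span under the peak. Peaks whose exons are
  terminal in every carrying transcript are excluded, which separates
  cassette exons from promoter/end variation. Mutually exclusive exons
  surface as two ce events.
* **ir** (retained intron) — the union of a structural rule (an intron of
  one transcript wholly contained in a single exon of another) and a
  coverage rule (a valley with non-zero mean coverage).
* **alt_end** — every end cluster other than the most proximal one.

The annotated GTF replaces each exon's feature with `exon` plus the labels
of events overlapping it, joined by `_` in the fixed order
alt_pro < alt5 < alt3 < ce < ir < alt_end (e.g. `exon_alt3_ce`). Transcript
rows carry the promoter group, per-class event counts the transcript
includes (`a5 a3 ce i`), the group totals (`a5t a3t cet it`) and the
fractional positions (`ap ae`). Identical input produces byte-identical
output.

## Usage proportions and the Beta model

Counts are grouped by promoter; a group needs at least one non-zero count
in both conditions or it is dropped (logged with the failing condition).
Within a group, each sample's counts are divided by the group total and
clipped into [0.001, 0.999]. For every isoform and condition independently
the clipped proportions are modelled as draws from Beta(α, β) with
Gamma(shape = 5, scale = 1) priors on both shapes — weakly informative
regularisation that shrinks extreme usage estimates at n = 3 replicates.
Though the underlying counts are compositional, the likelihood is Beta on
the proportions themselves (the count-level Beta-binomial variant is a
natural alternative; the proportion-level model is the one implemented and
tested here).

Sampling is random-walk Metropolis on (log α, log β), which keeps both
parameters positive and needs no derivatives. Defaults: 4 chains, 2,000
burn-in and 5,000 retained draws per chain, initial proposal SD 0.5 adapted
every 100 burn-in iterations toward a 20–40 % acceptance rate,
overdispersed prior-draw starts, seed 1337. A split-R̂ diagnostic is
computed per unit and warned about above 1.1. The sampler is vectorised
across all isoform × condition units, so a 500-isoform null study fits in
seconds on one CPU.

From matched condition posteriors the per-draw fold change
log₂(μ_aged/μ_young), with μ = α/(α+β), gives a posterior median, the 95 %
highest-posterior-density interval (shortest interval containing 95 % of
draws; ties resolve left-most) and P_up = P(log₂FC > 0). An isoform is
**significant** when the HPD interval strictly excludes zero *and*
max(P_up, 1 − P_up) > 0.95. Positive values mean higher usage in the second
(aged) condition; the direction convention is stated in every output.

**PS (percent spliced)** is the log₂ fold change of replicate-mean clipped
proportions between conditions; the posterior median is kept alongside as
the model-based point estimate. Each event inherits PS and significance
from the transcripts that physically include it (inclusion side) and from
those that exclude it (exclusion side), one row per (event, side,
transcript).

## Consequence classification

If an external CDS prediction table is supplied it is used verbatim;
otherwise the fallback ORF is the longest ATG-initiated, stop-terminated
reading frame across the three forward frames (ties to the 5′-most start),
with a 30 nt minimum to suppress micro-ORFs in synthetic sequence. CDS and
domain intervals are projected through the exon blocks to strand-aware
genomic segments; the projection is exactly invertible and tested as such.
A stop codon is "Last" when its 3′-most base falls in the transcript's
3′-most exon (this tie-break also settles the rare junction-spanning
codon). Domain hits are ingested from a whitespace-delimited per-domain
table (target = protein/transcript id, alignment coordinates in amino
acids). Per event: ORF overlap, stop-codon containment and location, the
overlapping domains, and whether the event touches a domain's first or last
codon projection (domain start / stop alteration — one consistent
operationalisation of a concept the upstream tools leave informal).

## Enrichment statistics

Unaffected (non-significant) events are the internal baseline fixing the
background frequency of each class. The report computes: up/down/unaffected
tallies per class and side with exact two-sided binomial tests (p = 0.5,
two-sided by summing point probabilities ≤ the observed one); proximal vs
distal TSS/TES usage (proximal ⇔ fractional position < 0.5, a configurable
cut) with two-sided Fisher tests, Bonferroni-corrected; single- vs
multi-transcript promoters with a Yates-corrected 2×2 chi-square plus
Fisher; and event-class composition tables for consequence strata with
plain Pearson r×c chi-squares plus one-vs-rest Fisher tests per class.
The Yates/plain pairing is deliberate: it is the combination that
reproduces the published 2×2 and r×c statistics simultaneously. Reported
odds ratios are sample cross-product ratios (0/∞ allowed at zero cells;
the conditional-MLE estimate is available behind a flag). Classes with zero
counts are reported but dropped from chi-squares with a warning.

## Synthetic data

The generator builds genes whose transcripts exhibit exactly the requested
event classes. Genes are assembled in transcription space as slots —
variant donor exon, variant acceptor, subset-only cassette exon, retained
intron — separated by constitutive exons and introns, with each slot
splitting the promoter group's isoforms into a fixed variant/reference
half. Multi-promoter genes stagger first-exon starts (30–60 nt) but share
the downstream backbone so promoter variation does not leak into end-site
clustering. Defaults: exons 80–300 nt, introns 100–1000 nt, genes placed on
`chrSyn1` with ≥ 10 kb gaps. Truth labels (class, position, including and
excluding transcripts) are emitted alongside.

Abundances are Dirichlet-multinomial: per sample, within-group proportions
~ Dirichlet(dispersion × μ_condition) with dispersion 50 and group totals
~ Poisson(depth = 1000), two conditions × 3 replicates by default. The
noise model deliberately differs from the inference model (Dirichlet on
compositions vs independent Betas), so recovery tests exercise a realistic
mismatch rather than a self-fulfilling one. Differential groups multiply
one isoform's usage odds by 2^effect (default 1.5) and renormalise.

Protein fixtures plant a unique ORF per transcript (background drawn from
{C, G, T} so the planted ATG is the only one — a synthetic-alphabet
convenience, not a biological sequence model), alternating stop codons
between the last and an upstream exon, and plant one domain per coding
transcript either over a cassette/retained-intron event or away from all
events, with the expected classification recorded.

What the generator does **not** emulate: read-level nanopore error,
truncated reads, mapping ambiguity, annotation errors in the collapsed
models, more than two conditions, or correlated usage across genes.
Passing tests therefore demonstrate correctness of the event definitions,
the inference machinery and the bookkeeping on clean structures — not
robustness to collapse artifacts in real long-read data.

## Numerical and testing choices

Problem sizes in the test suite and the reproduction script were chosen
desk-scale: detector/oracle equivalence runs on ~500 synthetic genes
(exact equality required, zero discrepancies tolerated); the null
calibration uses 500 isoforms × 3 replicates (observed significant-call
rate well under the 7 % bound, typically < 2 %); power uses a 0.3 → 0.7
usage shift on 200 isoforms (observed 100 %). The HPD routine is checked
against an exhaustive shortest-window search. Chi-square reproductions are
asserted to ±0.05 and odds ratios to ±0.005 of the published values.

Known limitations: alt5/alt3 semantics treat a transcript that merely
reads through a donor and then terminates as an excluding transcript (the
coverage signal cannot distinguish termination from read-through unless the
boundary coincides with an end cluster); mutually exclusive exon *pairing*
is not attempted (each exon is an independent ce event); no
multiple-testing procedure beyond Bonferroni; NMD rules and structural
modelling of domain loss are out of scope.
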