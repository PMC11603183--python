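# Methods

This note documents the statistical procedures, the synthetic study design,
the defaults and why they were chosen, and the known limits of what the
tests demonstrate.

## Study design assumed throughout

Twelve samples: 3 ground-control and 3 flight individuals at each of two
growth stages (tillering, heading), named TC1–3, TS1–3, HC1–3, HS1–3.
Group comparisons are 3-vs-3 within a stage; single-sample comparisons put
one flight individual against its three stage-matched controls. Three
molecular layers are carried: per-cytosine methylation counts, mRNA
abundances (FPKM-like), and miRNA abundances (TPM-like).

## Methylome

**Site levels.** Level = mc/(mc+uc) per cytosine; sites with coverage
below 4 reads are discarded. Context (CG/CHG/CHH, H ∈ {A,C,T}) is read
from the genomic trinucleotide on the cytosine's own strand — the standard
WGBS convention. Genome means are unweighted across sites, matching the
per-site level definition rather than weighting by coverage.

**Metagene profiles.** Each site is assigned to at most one bin of its
nearest gene (20 bins over a 2 kb upstream flank, 20 over the body, 20
over 2 kb downstream), strand-aware so bin 0 is always 5′. Empty bins are
reported missing, not zero.

**DMR caller.** A deliberately transparent two-stage procedure rather than
a smoothing-based one, so every step has an exact oracle:

1. pool counts within each side per site;
2. two-sided Fisher exact test on [mc_case, uc_case; mc_ctrl, uc_ctrl],
   computed by exact hypergeometric enumeration (vectorised);
3. candidate sites: p < 0.01 and |Δlevel| ≥ 0.1;
4. merge same-direction candidates with inter-site gap ≤ 200 bp into
   regions of ≥ 3 sites;
5. region p-value by Stouffer combination of signed site z-scores;
   regions with p < 0.05 are reported (raw p, matching the study
   convention; a BH column is available downstream).

All five thresholds are configuration keys. Single-sample DMRs use the
same caller with the one individual as the case side and the three pooled
control replicates as the reference — pooling maximizes control depth.
The promoter is defined as the 2 kb upstream of the TSS in transcription
sense only; the downstream 2 kb is profiled but not used for DMR→gene
assignment. A DMR overlapping ≥ 1 bp of promoter or body contributes to
that gene's DMG; genes with both hyper- and hypo-DMRs take the
dominant-|Δ| direction and carry an `ambiguous` flag.

## Differential expression

Group mode is a pragmatic stand-in for a negative-binomial framework:
Welch t on log2(x+1) with fold changes from side means, labeled
`group-welch` in all outputs. The single-sample path is the package's
core: `scipy.stats.ttest_1samp` of the control triple against the case
value (df = 2), two-sided. Gates: DEGs |log2FC| > 1 (strict) and p < 0.05;
miRNAs and MRs in single-sample mode p < 0.05 only. Fold changes use an
ε = 0.01 pseudo-count on the abundance scale (zero-handling is otherwise
undefined); the control **mean** is the single-sample baseline. Molecules
zero in every sample of either comparison side are removed first.
Zero-variance control triples cannot be tested and are routed to a
diagnostics note — never silently passed or failed.

Calibration statements about these tests refer to their statistical null:
the hypothesized (case) value equals the control population mean. Under
that null with normal noise the p-values are exactly t₂-distributed and
the 5% level is honest. When the case value is itself a noisy draw from
the control distribution, the statistic is distributed as 2·t₂ and the
nominal 5% test fires ≈ 16% of the time; this inflation is a property of
the published procedure, inherited intentionally, and it bounds what the
degree-based test can resolve (below).

## Single-sample networks

Aggregate network: Pearson correlation of log2(x+1) over all 12 samples
(Spearman available), diagonal zeroed, constant rows excluded with a
warning. LIONESS extracts sample q's network as
`e_q = N·e_all − (N−1)·e_all∖{q}`; the implementation is verified against
a brute-force leave-one-out construction to < 1e−10. Degrees count
partners with |e_q| ≥ τ, default τ = 0.8 applied to the LIONESS edge value
directly (these values are not bounded by [−1,1]); τ is recorded in all
outputs. Degree vectors span the 12 networks in the canonical sample
order; excluded molecules carry degree 0. The degree-differential test is
the same one-sample t (df = 2) on the control degree triple vs the flight
degree. mRNA and miRNA networks are built independently; a weighted-degree
option (Σ|w|) exists but is off by default.

**A structural limit worth knowing.** For an uncorrelated pair, the
LIONESS edge in sample q behaves like a product of standardized deviations,
so |e_q| ≥ 0.8 occurs for roughly a third of null pairs in any one network
regardless of sample size, while tightly co-expressed pairs sit near 1.
Binarized degrees therefore fluctuate from network to network for every
molecule, and the degree test's background positive rate sits near the
noisy-hypothesized-mean saturation (~16%) rather than 5%. Planted
module-rewiring shifts mean degrees by roughly the module-size difference,
which raises the planted call rate only modestly above that background
(measured ratio ≈ 0.7–1.5 across parameterizations). The acceptance
measurements report this enrichment ratio honestly; a practitioner should
treat single-sample degree calls as exploratory screening, not calibrated
inference.

## miRNA target scanning

Expectation score: mismatch 1.0, G:U wobble 0.5, gap/bulge 2.0, penalties
at miRNA positions 2–13 (1-based from the 5′ end) doubled; alignment
minimizes the total penalty. `score_duplex` is a dynamic program over
match/mismatch/gap states with the gap penalty taking the seed factor of
the next miRNA position to pair; the transcript scan reproduces it exactly
for the default ≤ 1-gap space using prefix sums of the gapless cost
matrix, making full-transcriptome scans cheap. Windows with expectation ≤ 5
are hits; overlapping hits of a pair collapse to the best site. T and U
are interchangeable. A central-mismatch (positions 10–11)
translation-inhibition annotation is emitted but never filtered on.
Differential miRNAs are paired with differential MRs they hit, separately
for expression evidence (DEmiR×DEMR, "Fold change") and interaction
evidence (DImiR×DIMR, "SSN"); same-direction pairs are retained with
`opposite=False`.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions every recovery and calibration figure refers to.

- **Genome**: 1 Mb random sequence at GC 0.45; 150 genes of 1–2 kb placed
  with ≥ 4 kb gaps so 2 kb flanks never collide; 12 genes carry the
  packaged MR catalog ids. A 12% random subset of genomic cytosines is
  emitted per sample (planted sites always included), emulating sparse
  coverage while keeping desk-scale runtimes.
- **Methylome**: per-site baseline levels beta-distributed around context
  means CG 0.6 / CHG 0.3 / CHH 0.1 (concentration 30, giving beta-binomial
  overdispersion); depth Poisson(20); flight samples shift by the planted
  Δ inside planted intervals only, clamped to [0,1] with a warning. The
  default plan plants 14 regions (more hypo- than hyper-methylated, CHH
  effects small), each 10 sites / depth 20 / ≤ 400 bp, placed inside gene
  promoters or bodies so DMG assignment has signal.
- **Expression**: lognormal baselines (CV 0.2); genes partitioned into
  correlated modules (within-module Pearson ≈ 0.9 via a shared latent
  factor per module per sample) so the aggregate network has real edges.
  Planted DEGs multiply flight values by 2^±2 (5% up, 5% down); planted
  DIGs (10%, disjoint from DEGs) draw their module factor from a different
  module in flight samples only, leaving expected levels unchanged —
  isolating the interaction signal from the expression signal. A few
  all-zero molecules exercise the zero filter.
- **Targets**: random 21-nt miRNAs rejection-sampled so no unplanted pair
  scores ≤ 5 anywhere; 8 planted sites are exact reverse complements with
  one non-seed mismatch (expectation exactly 1). Four planted pairs are
  additionally given opposite-direction expression shifts (miRNA up, MR
  down) so the pairing stage has recoverable signal.
- **Determinism**: one seed feeds four named child streams (genome /
  methylome / expression / targets); fixed seed ⇒ byte-identical output
  files. A self-check verifies every truth entry is realized in the
  emitted artifacts.

What the generator does **not** emulate: read-level artifacts (bisulfite
conversion errors, mapping bias), linkage between methylation and
expression (planted DMRs do not causally change planted DEGs), stage- or
individual-specific effect sizes, and realistic co-expression topology
beyond block modules. Passing recovery tests therefore demonstrates the
callers' correctness and calibration on data satisfying their assumptions,
not performance on real sequencing data.

## Numerical choices

- Fisher two-sided p sums hypergeometric outcomes with probability ≤
  observed × (1 + 1e−7), the convention of mainstream implementations.
- Stouffer z uses `isf(p/2)` with p clipped at 1e−300 to avoid underflow.
- Degrees and set operations are order-independent; reruns under one seed
  are byte-identical (verified file-by-file in the tests).
- Strict inequalities at gates: a molecule at exactly twofold is reported
  with `passed=False`.
- 1-based inclusive coordinates internally; BED conversion confined to one
  function pair.

## Problem sizes

Default synthetic study: 150 genes, 80 miRNAs, 1 Mb genome, ~54k cytosine
records × 12 samples; the full pipeline runs in well under a minute on one
CPU, and the complete test suite in a few minutes. These sizes were chosen
so planted effects are estimated with enough sites/molecules for stable
recovery statistics while keeping iteration fast; all of them scale up via
`SimConfig`.
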