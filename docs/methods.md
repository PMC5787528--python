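# Methods

This note documents the models, defaults and numerical choices behind
`cacsomatic`, and what the synthetic-data experiments do and do not show.

## Tumor-only variant calling

The caller consumes per-base pileup observations (sample, contig, 1-based
position, reference base, observed allele, base quality, mapping quality,
read-position fraction, strand). Alignment, duplicate removal and pileup
extraction are upstream concerns; the observation TSV is the package's
primary input dialect, and BAM decoding is deliberately out of scope.

**Quality skips.** Observations with base quality < 20 or mapping quality
< 10 are excluded from all counts. Indel observations have no single base
call, so they are exempt from the base-quality skip but not the
mapping-quality skip.

**Calling clauses.** Every threshold is strict (the quantity must exceed
it). SNV: depth > 50, VAF > 5%, and three bias tests each with p > 0.01.
INDEL: depth > 50, VAF > 10%, supporting reads > 20, no bias tests.
Boundary tests lock the strictness in (50 fails, 51 passes; 5.0% fails;
20 supporting reads fail; detection in exactly 8 samples survives the
recurrence filter, 9 does not).

**Bias tests.** The three "bias" quantities are two-sided Wilcoxon rank-sum
p-values comparing alt-supporting against reference-supporting reads on one
attribute each (base quality, mapping quality, read-position fraction) —
the convention of mainstream pileup callers, chosen because it matches the
named attributes and yields p-values commensurate with a 0.01 cutoff. The
shared engine uses exact enumeration when the smaller group has ≤ 8 values
and the pooled data are tie-free, and the tie-corrected normal
approximation with continuity correction otherwise; fully tied data give
p = 1. When a site has no reference-supporting reads (near-homozygous alt),
the bias tests are undefined; they are treated as passing and the VCF
records a `BIASNA` flag, since discarding would delete true high-VAF
variants.

**Cohort filters.** Candidate alleles matching a supplied common-variant
site list (allele-exact) are tagged `dbsnp` — the tumor-only proxy for
germline subtraction. The recurrence filter counts, once over the full
cohort, the samples in which each (contig, pos, ref, alt) is detected and
tags the allele `recurrent` everywhere if that count exceeds 8. "Detected"
has two defensible readings and `recurrence_basis` selects one:

* `raw` (default): the allele meets the per-sample evidence clauses
  (depth/VAF/support), regardless of bias or dbSNP status. This is the
  panel-of-normals convention — an artifact is identified by its raw
  presence across samples.
* `passed`: the allele passes every other filter in that sample.

The default is `raw` because the `passed` reading is not robust: a single
sporadic bias-test rejection in one sample drops a 9-sample artifact to 8
detections and lets it through everywhere. Under null attributes each bias
test rejects with probability ≈ 0.01, so a 9-of-9 requirement fails in
roughly a quarter of cohorts; the raw reading removes the artifact class
deterministically. Both readings are implemented and tested.

**Auditability.** Filters tag calls instead of deleting them; `passed`
means the tag set is empty and the VCF FILTER column carries the full set
(`lowdepth`, `lowvaf`, `lowsupport`, `bqbias`, `mqbias`, `rpbias`, `dbsnp`,
`recurrent`). The run manifest additionally counts each rejected call once
under its first failing tag in the documented clause order (dbsnp,
lowdepth, lowvaf, lowsupport, bqbias, mqbias, rpbias, recurrent) so that
candidates = passed + Σ per-tag counts holds exactly.

## Mutation spectra and methylation trend

Substitutions are strand-collapsed onto the pyrimidine reference base and
annotated with their 5' and 3' neighbors, giving 96 classes ordered C>A,
C>G, C>T, T>A, T>C, T>G, then 5' base, then 3' base alphabetically (the
community signature ordering; exhaustive enumeration over all 192 stranded
inputs confirms each class is hit exactly twice). Calls at contig termini
have no context and are excluded with a count. The CpG summary reports the
16-class C>T total, the 4-class N[C>T]G total, and their fractions.

The methylation trend test bins CpG sites by methylation level (default:
five equal-width bins on [0, 1], scored at midpoints — the binning is a
package choice; finer binning changes power only marginally) and applies
the Cochran–Armitage trend statistic in closed form, one-sided for an
increasing trend by default (the direction of the deamination hypothesis);
a two-sided variant is available. Zero trend variance (all CpGs in one
occupied bin) raises an undefined-test error. The closed form is verified
in tests against a 10⁵-shuffle permutation null.

TpT→GpT burden sums the four T[T>G]N classes per sample, strand-collapsed
(a plus-strand ApA→ApC event is the same class); samples with 20 or more
such SNVs are flagged (inclusive boundary). Cohort spectra exclude samples
above a configurable hypermutation cutoff (default 300 SNVs).

## Association statistics

Fisher's exact test uses the point-probability two-sided rule (sum of all
hypergeometric outcomes no more probable than the observed table), the
dominant software convention; tests verify agreement with full enumeration
to 1e-12 for every table with N ≤ 30. The odds ratio is the sample ad/bc
with ∞/0 conventions at zero cells. Wilcoxon comparisons share the caller's
rank-sum engine; durations in months rarely tie, so the exact path applies
at small n and the tie-corrected approximation otherwise. Tumor stage is
treated as an ordered numeric covariate (0–4) with NA dropped pairwise.
Benjamini–Hochberg q-values (q(i) = min over j ≥ i of (m/j)·p(j), clipped at
1) are applied within each declared test family, never across families.
Note BH is *not* idempotent — re-applying the step-up formula to q-values
rescales them again — so the tested invariants are q ≥ p, q ≤ 1, rank
monotonicity and tie stability.

## Expression clustering

FPKM-UQ follows the TCGA convention: count · 10⁹ / (gene length in bp ·
UQ), with UQ the 75th percentile of the sample's nonzero gene counts; a
sample with all-zero counts is an error. Genes not expressed in every
sample are removed, values are log10(1 + x)-transformed, and each gene is
z-scored with the n−1 denominator (zero-variance genes are dropped with a
warning — they carry no clustering information and would divide by zero).
Samples are clustered agglomeratively with Euclidean distance and Ward's
variance-minimizing linkage, heights reported on the distance scale (two
singletons merge at their Euclidean distance); this is the squared-distance
Lance–Williams dialect, pinned down in tests by a from-scratch
implementation that recomputes cluster variances at every step. k is a
parameter (default 2) with no automatic selection. A provenance tag on the
matrix records its stage (counts → fpkm_uq → log → scaled) and only moves
forward.

## The synthetic cohort

The generator's defaults define the study conditions: 20 samples, an
8-gene panel of 250 bp intervals (2000 sites) on a 26 kb random reference
at GC 0.45, per-site depth Poisson(150).

* Reference-supporting reads draw base quality from a discretized
  Normal(35, 3) clipped to [2, 41], mapping quality 60 with 2%
  contamination at 0 (exercising the MQ skip), read-position fraction
  Uniform(0, 1). True-variant alt reads draw from the same distributions,
  so the three bias filters are separably testable.
* Germline: each panel site is population-polymorphic with probability
  0.003; each sample is a heterozygous carrier with probability 0.7
  (alt count Binomial(depth, 0.5)); 95% of polymorphic sites appear in
  the mini common-variant list. Unlisted germline is deliberately left in:
  it is *scored* (as residual passed calls) rather than removed, mirroring
  the limits of database-only germline subtraction.
* Somatic: per gene, per sample, an event with probability 0.6; SNV VAF
  Uniform(0.15, 0.40); 20% of events are 1–3 bp indels at VAF
  Uniform(0.20, 0.50). The indel floor is 0.20 because at depth 150 the
  support > 20 clause implies VAF ≳ 0.14; lower floors would plant events
  the caller's own printed clauses must reject.
* FFPE artifacts: per C/G site, per sample, probability 0.01 of a C>T
  (G>A on the minus strand) artifact at drawn VAF Uniform(0.01, 0.04),
  with the realized alt count floored so the observed VAF stays below the
  5% clause — FFPE noise stresses the VAF filter, not the bias filters.
* Attribute-shifted artifacts: per site probability 0.0015, VAF
  Uniform(0.08, 0.20) (above the VAF clause so only a bias test can catch
  them), alt read positions Uniform(0, 0.1).
* Recurrent artifact: one allele planted in exactly 9 of 20 samples at VAF
  Uniform(0.15, 0.35) with null attributes — only the recurrence filter
  can remove it.
* Sequencing errors: each remaining read miscalled with probability 0.002,
  uniformly to a wrong base; these stay far below every calling clause.

The methylation model mutates each reference CpG with probability
base_rate + slope · methylation (defaults 0.01 + 0.09·m), methylation
Uniform(0, 1) when not supplied. The expression model is log10-normal
(gene means N(1, 0.5), noise SD 0.3) with 50 module genes shifted +1.5
(5 noise SDs) in the 6-sample cluster — a strongly separated subtype that
Ward clustering should recover exactly. Clinical covariates mirror the
margins of a 90-patient IBD-cancer cohort (64% UC; histology 68/32;
stage 4/14/40/29/7/6%); IBD durations are Gamma(shape 4) with mean 328
months in carriers of the designated gene (default RNF43) and 215
otherwise.

**What the synthetic experiments show — and don't.** Passing the
planted-truth suite demonstrates that each filter removes its designated
artifact class and spares well-separated true variants under this
generative model. Real FFPE panels differ in ways the model omits: depth
varies systematically with GC and capture efficiency, artifact VAFs are
not neatly bounded away from thresholds, mapping quality is continuous,
errors are context-dependent, and tumor purity/subclonality push true VAFs
toward the 5% clause. Recall/precision figures on synthetic data are
therefore statements about internal consistency, not expected field
performance.

## Problem sizes and runtime choices

The default cohort (20 samples × 2000 sites × depth 150 ≈ 6M observations)
simulates and calls in well under a minute on one CPU; the demo pipeline
config uses 10 samples over a 4-gene panel at depth 120 so an end-to-end
run stays around ten seconds. Trend-test power uses 100 replicates of 10⁴
CpGs; null calibration 400 replicates of 2000 CpGs; the Ward oracle 50
random fixtures with ≤ 10 samples. These sizes give 3-SD Monte-Carlo
tolerances tight enough to catch real defects while keeping the whole
suite around a minute.

## Known limitations

* No BAM/CRAM input, no paired tumor–normal mode, no local realignment or
  base-quality recalibration, no copy-number or fusion analysis.
* The recurrence filter's `raw` basis can, in principle, tag a true
  hotspot mutation shared by more than 8 samples; on targeted panels of
  recurrently mutated genes this is a real trade-off, and the `passed`
  basis plus a lower `max_recurrence` are both configurable.
* The Fisher two-sided rule and the Wilcoxon tie handling are conventions;
  other software (mid-p, double-one-sided) will differ in the third digit.
* Indel representation is single-allele pileup spelling; complex and
  multi-allelic indels at one site are treated as distinct alleles.
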