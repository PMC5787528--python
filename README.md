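# cacsomatic

Tumor-only somatic variant calling and cohort statistics for deep targeted
sequencing of colitis-associated cancer (CAC), with a synthetic-cohort
generator that provides planted ground truth for every pipeline stage.

## The problem

Colorectal and anal cancers arising in long-standing inflammatory bowel
disease (ulcerative colitis or Crohn's disease) are typically archived as
FFPE blocks without matched normal tissue. Calling somatic mutations from
deep targeted panels on such material means separating true variants from
four confounders: germline polymorphisms, FFPE deamination artifacts
(low-VAF C>T), alignment/sequencing artifacts whose supporting reads carry
shifted quality attributes, and platform artifacts that recur across many
samples. Downstream, the cohort questions are statistical: which genes
associate with disease subtype, duration of colitis, histology, and extent;
what the trinucleotide mutation spectrum says about mutational mechanism
(CpG deamination, TpT→GpT excess); and whether expression profiles split
the tumors into subtypes enriched for Wnt-pathway mutations.

This package implements that whole chain as a tested library:

* **`cacsomatic.calling`** — pileup-based tumor-only caller. Observations
  with base quality < 20 or mapping quality < 10 are skipped; an SNV is
  called when depth > 50, VAF > 5%, and each of three read-attribute bias
  tests (base quality, mapping quality, read position; two-sided Wilcoxon
  rank-sum of alt- vs reference-supporting reads) has p > 0.01; an indel
  when depth > 50, VAF > 10% and support reads > 20. Known common variants
  are tagged `dbsnp`; alleles detected in more than 8 samples are tagged
  `recurrent`. All comparisons are strict, all filters tag rather than
  delete, `PASS` means "no tags".
* **`cacsomatic.spectrum`** — the 96 pyrimidine-centered trinucleotide
  substitution classes, CpG C>T summaries, a Cochran–Armitage trend test of
  mutation rate over methylation bins
  (T = Σ sᵢ(rᵢ − nᵢR/N), Var = (R/N)(1−R/N)[Σ nᵢsᵢ² − (Σ nᵢsᵢ)²/N]),
  and per-sample TpT→GpT burden flags (≥ 20).
* **`cacsomatic.association`** — Fisher's exact test (point-probability
  two-sided rule), Wilcoxon rank-sum on clinical covariates,
  Benjamini–Hochberg q-values, per-gene cohort-frequency comparisons.
* **`cacsomatic.expression`** — FPKM-UQ conversion
  (count·10⁹ / (length·UQ), UQ = 75th percentile of a sample's nonzero
  counts), expressed-in-all filtering, log10(1+x) + per-gene z-scaling, Ward
  clustering of samples (Euclidean distance, variance-minimizing linkage,
  heights on the distance scale), and cluster–mutation association.
* **`cacsomatic.simulate`** — generates every input with known truth:
  planted germline/somatic variants, FFPE-like artifacts, attribute-shifted
  artifacts, recurrent artifacts, methylation-driven CpG mutations, a
  two-cluster expression matrix, and clinical covariates.
* **`cacsomatic.io` / `cacsomatic.pipeline` / `cacsomatic.cli`** — TSV/FASTA/
  VCF/bedMethyl readers and writers, a one-config orchestrator with a
  reproducibility manifest, and the `cacsomatic` command.

## Worked example

`analysis/` holds numbered drivers that run the full study on synthetic
data. From the repository root:

```
$ python analysis/01_simulate_and_call.py
simulated 20 samples over a 8-gene panel, mean depth 150
passed calls: 98  recall 1.000  precision 1.000
artifact capture: FFPE lowvaf 1.00, bias-shifted 1.00, recurrent 1.00, dbSNP germline 1.00
```

All 98 planted somatic events are recovered with no false positives; every
FFPE artifact is caught by the VAF clause, every attribute-shifted artifact
by a bias test, the 9-sample recurrent allele by the recurrence filter, and
every dbSNP-listed germline call by the common-variant filter.

```
$ python analysis/03_clinical_associations.py
published contingency tables, re-tested:
  TP53 mutated x CD/UC: p=2.27e-03
  no mutation x CD/UC: p=1.77e-05
  anal mucinous x mutation status (CD): p=1.77e-02
  APC x histology: p=3.10e-02
  APC x extent of colitis: p=1.69e-03
  Wnt mutation x expression cluster: p=3.45e-02
synthetic cohort, RNF43 x duration: mean shift 102 months, p=0.14, q=0.845
```

The six published contingency tables all clear their reported significance
bounds. On the 20-sample synthetic cohort the planted RNF43–duration shift
(means 328 vs 215 months) is directionally recovered but not significant —
expected, since the published effect was detected in a 90-patient cohort.

```
$ python analysis/04_expression_clustering.py
Ward clustering over 1000 genes: cluster sizes [6, 11], agreement with planted labels 100%
Wnt-mutation enrichment between clusters: table [[5, 1], [1, 10]], p=0.00541
```

The demo pipeline runs all stages under one config:

```
cacsomatic run-all --config configs/demo.yaml
```

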