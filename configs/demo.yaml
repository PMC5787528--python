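# Demo pipeline config: a small synthetic cohort that runs end-to-end on one
# CPU in well under five minutes.  See docs/methods.md for what each stage does.
out_dir: results/demo
seed: 0
log_level: INFO

simulate:
  n_samples: 10
  ref_length: 12000
  depth_mean: 120
  panel:
    - [TP53,  panel_ref, 1001, 1200]
    - [APC,   panel_ref, 3001, 3200]
    - [RNF43, panel_ref, 6001, 6200]
    - [KRAS,  panel_ref, 9001, 9200]
  recurrent_artifact_n_samples: 9

thresholds: {}          # defaults: the strict deep-panel clauses
recurrence_basis: raw

trend_bins: 5
trend_side: one
tpt_flag_threshold: 20
hypermutated_cutoff: 300
methylation_slope: 0.09
methylation_base_rate: 0.01

cluster_k: 2
expression:
  n_genes: 1000
  cluster_sizes: [6, 11]
  n_module_genes: 50
  effect: 1.5

duration_mean_carrier: 328.0
duration_mean_noncarrier: 215.0
carrier_gene: RNF43
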