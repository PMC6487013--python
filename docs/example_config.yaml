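# Example run configuration for `sowscan all --config example_config.yaml`.
# Omitted simulate keys fall back to SimConfig defaults (study-scale:
# 4,200 animals, 5,000 SNPs on 18 x 10 Mb autosomes).
seed: 42
outdir: sowscan_demo

simulate:
  n_founders: 60
  n_generations: 3
  n_animals_per_gen: 200
  n_snps: 1500
  n_chromosomes: 6
  chrom_length_bp: 5000000
  n_qtl: 3
  qtl_variance_fraction: 0.4
  cnv_n_latent_regions: 20
  cnv_carrier_freq_range: [0.05, 0.3]
  records_per_sow_range: [2, 6]

# analysis thresholds
variance_threshold_pct: 1.0   # report windows explaining > 1% of additive variance
n_iter: 2                     # WssGWAS iterations (1 = unweighted ssGWAS)
blend_beta: 0.05              # G blended with 5% of A22
window_bp: 1000000
min_snps_per_call: 3
min_freq: 0.005
min_recurrence: 0.1
reml_tol: 1.0e-8
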