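# Packaged end-to-end demo: the GWAS-stage design mirrors the pooled
# CRC sub-study (630 cases / 690 controls in 15-sample pools, triple
# technical replicates) with 2,000 SNPs in 4-SNP LD blocks and ten
# planted effect blocks at allelic OR = 2.0; the replication stage uses
# an independent cohort of comparable size to the extended cohorts.
seed: 1
panel:
  n_snps: 2000
  maf_range: [0.2, 0.5]
  block_length: 4
  within_block_r2: 0.9
  spacing: 25000
  n_reference: 200
effects:
  n_blocks: 10
  allelic_or: 2.0
gwas:
  n_cases: 630
  n_controls: 690
  pool_size: 15
  n_replicates: 3
  noise_cv: 0.05
  gain: 1000.0
  n_outlier_pools: 1
  outlier_shift: 0.1
replication:
  n_cases: 890
  n_controls: 2190
degradation:
  snp_missing_rate: 0.01
  ind_missing_rate: 0.005
  error_rate: 0.001
  n_hwe_violating: 5
thresholds:
  z_threshold: 3.5
  p_index: 1.0e-3
  p_proxy: 1.0e-3
  r2_min: 0.7
  window_bp: 100000
  p_eligible: 0.01
  max_snp_missing: 0.05
  max_ind_missing: 0.05
  hwe_p_min: 1.0e-3
  bh_alpha: 0.05
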