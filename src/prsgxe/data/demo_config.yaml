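# Demo pipeline configuration: small synthetic cohorts, runs in seconds.
seed: 7
qc_preset: default
alpha_refine: 0.05
scan_covariates: none
grid:
  n: 100
clump:
  window_kb: 250.0
  r2_max: 0.2
simulation:
  n_discovery: 800
  n_test: 300
  n_snps: 200
  n_causal: 10
  h2: 0.3
  ld_rho: 0.4
  gxe:
    bX: 0.0
    bM: 0.0
    bXM: -0.33
    noise_sd: 1.0
bootstrap:
  enabled: false
imputation:
  enabled: false
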