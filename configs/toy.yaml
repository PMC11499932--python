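# Toy end-to-end configuration: a small inversion cohort that runs the
# whole pipeline (simulate -> breakpoints -> genotype -> popgen -> geneflux)
# in well under a minute. Coordinates are 0-based half-open here (internal
# convention); all stage outputs report 1-based inclusive.
seed: 1
cohort:
  n_N: 8
  n_S: 8
  n_het: 2
  n_outgroup: 1
  L: 300000
  inversion_interval: [75000, 195000]
  Ne: 10000
  T_split_gen: 300000
  T_outgroup_gen: 2000000
  flux_rate: 1.0
  flux_tract_len: 10000
  missing_rate: 0.02
  seed: 1
assembly:
  dup_len_bp: 3000
  dup_identity_pct: 92
  core_len_bp: 1000
breakpoints:
  min_block_len: 2500
  min_inversion_len: 20000
genotyping:
  window_snps: 40
  min_sites: 10
popgen:
  window_bp: 20000
geneflux:
  maf_floor: 0.2
  daf_threshold: 0.95
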