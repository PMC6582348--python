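name: anchored_plasmid_accumulation
genome:
  length_bp: 13500
  circular: true
  barriers_bp:
  - 0
  topoisomerases:
  - name: topoI
    sign: 1
    sigma0: -0.04
    width: 0.012
    k_basal_per_s: 0.001
    concentration_uM: 0.041
    reference_concentration_uM: 0.041
  - name: gyrase
    sign: -1
    sigma0: 0.01
    width: 0.025
    k_basal_per_s: 0.001
    concentration_uM: 0.0
    reference_concentration_uM: 0.1
  units:
  - id: long_gene
    tss_bp: 600
    terminator_bp: 12600
    strand: +
    k_on_per_s: 0.005
    active: true
    response:
      variant: positive_repressed
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
      sigma_r: 0.19
      epsilon_r: 0.05
params:
  duration_s: 25200.0
  dt_s: 2.0
  unit_length_bp: 60
  rnap_speed_nt_per_s: 30.0
  gamma: 0.2
  rnap_pool: 4
  initial_sigma: 0.0
  burn_in_s: 0.0
  seed: 0
  sampling_interval_s: 120.0
  clamp_sigma: false
interventions:
- time_s: 18000.0
  target: topo:gyrase:concentration_uM
  value: 0.1
meta:
  phase1_duration: 18000.0
  unit: long_gene
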