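name: toy_genome_w2.5
genome:
  length_bp: 30000
  circular: true
  barriers_bp:
  - 0
  - 10020
  - 19980
  topoisomerases:
  - name: gyrase
    sign: -1
    sigma0: 0.01
    width: 0.025
    k_basal_per_s: 0.001
    concentration_uM: 0.25
    reference_concentration_uM: 0.1
  - name: topoI
    sign: 1
    sigma0: -0.04
    width: 0.012
    k_basal_per_s: 0.001
    concentration_uM: 0.025
    reference_concentration_uM: 0.041
  units:
  - id: geneDL
    tss_bp: 3000
    terminator_bp: 2040
    strand: '-'
    k_on_per_s: 0.0014142
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: probe_div
    tss_bp: 5040
    terminator_bp: 5100
    strand: +
    k_on_per_s: 0.0014142
    active: false
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: geneDR
    tss_bp: 7020
    terminator_bp: 7980
    strand: +
    k_on_per_s: 0.0014142
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: geneCL
    tss_bp: 12000
    terminator_bp: 12960
    strand: +
    k_on_per_s: 0.0014142
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: probe_conv
    tss_bp: 15000
    terminator_bp: 15060
    strand: +
    k_on_per_s: 0.0014142
    active: false
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: geneCR
    tss_bp: 17040
    terminator_bp: 16080
    strand: '-'
    k_on_per_s: 0.0014142
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: geneTL
    tss_bp: 22020
    terminator_bp: 22980
    strand: +
    k_on_per_s: 0.0014142
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: probe_tand
    tss_bp: 25020
    terminator_bp: 25080
    strand: +
    k_on_per_s: 0.0014142
    active: false
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: geneTR
    tss_bp: 27000
    terminator_bp: 27960
    strand: +
    k_on_per_s: 0.0014142
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
params:
  duration_s: 5700.0
  dt_s: 2.0
  unit_length_bp: 60
  rnap_speed_nt_per_s: 30.0
  gamma: 0.2
  rnap_pool: 8
  initial_sigma: -0.03
  burn_in_s: 1800.0
  seed: 0
  sampling_interval_s: 60.0
  clamp_sigma: false
interventions:
- time_s: 3600.0
  target: topo:gyrase:concentration_uM
  value: 0.05
meta:
  waiting_time_min: 2.5
  k_on: 0.0014142
  gyrase_conc_M: 2.5e-07
  shock_time: 3600.0
  probe_classes:
    probe_div: divergent
    probe_conv: convergent
    probe_tand: tandem
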