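name: divergent_cassette
genome:
  length_bp: 10020
  circular: true
  barriers_bp:
  - 0
  - 5040
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
  - id: tufB
    tss_bp: 2340
    terminator_bp: 1440
    strand: '-'
    k_on_per_s: 0.0033333333333333335
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: tetP
    tss_bp: 2640
    terminator_bp: 3540
    strand: +
    k_on_per_s: 0.005
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
params:
  duration_s: 3600.0
  dt_s: 2.0
  unit_length_bp: 60
  rnap_speed_nt_per_s: 30.0
  gamma: 0.2
  rnap_pool: 8
  initial_sigma: -0.03
  burn_in_s: 1200.0
  seed: 0
  sampling_interval_s: 60.0
  clamp_sigma: false
interventions: []
meta:
  tetP_kon: 0.005
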