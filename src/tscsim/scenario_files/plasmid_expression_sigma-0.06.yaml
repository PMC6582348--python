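name: plasmid_sigma_-0.060
genome:
  length_bp: 5040
  circular: true
  barriers_bp: []
  topoisomerases: []
  units:
  - id: pelE
    tss_bp: 600
    terminator_bp: 1800
    strand: +
    k_on_per_s: 0.0005
    active: true
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
  - id: ampR
    tss_bp: 4500
    terminator_bp: 3900
    strand: '-'
    k_on_per_s: 0.0005
    active: false
    response:
      variant: standard
      sigma_t: -0.042
      epsilon: 0.005
      m: 2.5
params:
  duration_s: 14400.0
  dt_s: 2.0
  unit_length_bp: 60
  rnap_speed_nt_per_s: 30.0
  gamma: 0.2
  rnap_pool: 10
  initial_sigma: -0.06
  burn_in_s: 0.0
  seed: 0
  sampling_interval_s: 60.0
  clamp_sigma: false
interventions: []
meta:
  sigma: -0.06
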