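# Default study configuration (all values also live in the dataclass
# defaults; this file documents them and is a template for overrides).
design:
  n_participants: 16        # power analysis of the original design
  n_blocks: 10
  trials_per_block: 35      # 7 repetitions x 5 numerosities per block
  adaptor_high_flashes: 64  # ~8 Hz over 8 s
  adaptor_low_flashes: 16   # ~2 Hz over 8 s
  adaptor_duration_ms: 8000.0
  test_duration_ms: 4000.0  # tagging frequency = numerosity / 4 Hz
  isi_ms: 1000.0
  flash_duration_ms: 40.0
  jitter_fraction: 0.15     # +/-15% of the nominal inter-flash interval

behavior:
  gain_high: 0.925          # multiplicative underestimation after High adaptor
  gain_low: 1.075           # overestimation after Low; difference = 15%
  participant_gain_sd: 0.05
  response_noise_sd: 1.2    # flashes, per trial

eeg:
  ssvep_amp_low: 1.0        # microvolt at the effect sensors
  ssvep_amp_ratio_high: 1.3
  effect_sensors: [POz, O2, C3, Cz]
  coupling_pairs: [[C3, CP5], [CP5, CP6], [CP5, POz], [C3, PO7]]
  coupling_strength_high: 0.6
  coupling_strength_low: 0.2
  coupling_amp_uv: 15.0
  coupling_gain: 1.55        # nominal strength -> injected band correlation
  coupling_background: 0.7   # condition-independent network correlation
  noise_exponent: 1.0       # 1/f spectral slope
  noise_rms_uv: 10.0
  topo_sigma_rad: 0.07      # spatial falloff of the ssVEP topography
  shared_noise_frac: 0.92   # variance fraction of low-rank shared noise
  n_shared_sources: 4

n_trials_per_cell: 8        # reduced desk-scale profile; 35 = full design
behavior_link: 0.5          # ssVEP-ratio / behavioral-gain coupling
n_permutations: 15000
q: 0.05
ptp_threshold_uv: 150.0
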