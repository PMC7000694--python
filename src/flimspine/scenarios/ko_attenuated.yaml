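# Knockout-like phenotype: lower basal binding fraction, attenuated
# activation and reduced sustained volume change; geometry and acquisition
# identical to wt_default.
name: ko_attenuated
geometry:
  shape: [128, 128]
  pixel_size_um: 0.1
  dendrite_radius_um: 0.25
  spines:
    - {arclength_um: 4.6, radius_um: 0.35, side: 1}
    - {arclength_um: 2.2, radius_um: 0.30, side: -1}
    - {arclength_um: 1.0, radius_um: 0.30, side: 1}
  stimulated_index: 0
  neck_length_um: 0.3
  spine_brightness: 1800.0
  dendrite_brightness: 1400.0
  background_rate: 2.0
  psf_sigma_um: 0.2
  radius_jitter: 0.05
program:
  uncaging_time_s: 0.0
  volume_transient_amplitude: 0.8
  volume_sustained_amplitude: 0.1
  volume_transient_decay_tau_s: 150.0
  pad_baseline: 0.08
  pad_transient_amplitude: 0.03
  pad_sustained_amplitude: 0.015
  pad_transient_decay_tau_s: 120.0
  spread_length_um: 2.0
  spread_onset_delay_s: 120.0
acquisition:
  frame_shape: [128, 128]
  z_slices: 3
  z_spacing_um: 1.0
  frames_averaged: 6
  frame_times_s: {start: -480.0, stop: 1500.0, step: 30.0, skip: [0.0, 59.0]}
  n_bins: 64
  tcspc_window_ns: 12.5
  tau_G: 0.2
  true_t0: 1.2
  calibration: {tau_D: 2.6, tau_AD: 1.1}
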