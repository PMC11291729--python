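# Demo: simulated ciliary-like inside-out patch, one 12 s sweep per voltage.
# Conductance and gating rates emulate an oxysterol-potentiated polycystin
# channel; run with  `patchkit run --config examples/ciliary_patch.yaml`.
mode: single_channel
seed: 2024
out_dir: patchkit_demo_sc
simulate:
  conductance_ps: 96.5      # unitary conductance, pS
  reversal_mv: 0.0
  opening_rate: 50.0        # C->O rate at 0 mV, 1/s
  closing_rate: 50.0        # O->C rate, 1/s
  n_channels: 1
  duration_s: 12.0
  voltages: [-100, -80, -60, -40, -20, 0, 20, 40, 60, 80, 100]
acquisition:
  sampling_rate_hz: 10000.0
  filter_cutoff_hz: 5000.0
  noise_sd_pa: 0.25
analysis:
  n_components: 2
  window_s: 10.0
  window_start_s: 1.0       # skip the first second before the Popen window
  fit_range_mv: [-100, 100]
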