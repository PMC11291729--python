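# Demo: simulated whole-cell step family (-100..+180 mV, 20 mV, 150 ms)
# with outwardly rectifying steady-state current and fast activation.
mode: whole_cell
seed: 2024
out_dir: patchkit_demo_wc
acquisition:
  sampling_rate_hz: 10000.0
  filter_cutoff_hz: 5000.0
  noise_sd_pa: 2.0          # macroscopic baseline noise, pA
whole_cell:
  capacitance_pf: 20.0
  max_density_pa_per_pf: 139.9   # density at the +180 mV reference step
  tau_ms: 0.06                   # activation time constant
  reversal_mv: 0.0
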