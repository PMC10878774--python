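# Template run configuration for the ectsim CLI.
# All numeric keys carry their unit in the key name.

protocols:
  - name: hf_50x50          # 50 bursts x 50 bipolar 2 us pulses, 1 Hz
    field_kV_per_cm: 1.4
  - name: mono_8x100us      # conventional ECT pulses
    field_kV_per_cm: 1.2
  - name: mono_8x5ms
    field_kV_per_cm: 0.6
concentrations_uM: [0.0, 10.0, 30.0, 50.0]
t_end_min: 25.0             # readout delay after the last pulse

# parameters:               # optional overrides of the model defaults
#   sigma_ext_S_per_m: 1.4
#   r_um: 7.5

solver:
  rtol: 1.0e-8
  atol: 1.0e-12
  gap_switch_threshold_tau: 100.0
  t_end_reference: train_end

synthetic:
  n_replicates: 4
  uptake_cv: 0.2
  baseline_slope_per_uM: 1.0e5
  kill_rate_k_per_molecule: 7.0e-8
  plating_efficiency_pe0: 0.8
  cells_plated: 100
  wells: 3

output_dir: ectsim_out
seed: 0
log_level: INFO
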