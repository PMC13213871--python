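# Example configuration for `hemoforce run-all`.
# Without an `input` section a phantom is simulated; point `input` at NIfTI
# velocity components + JSON sidecar/annotation to process real data.
out_dir: hemoforce_out
seed: 1
constants:
  rho: 1060.0      # blood density, kg/m^3
  mu: 0.004        # dynamic viscosity, Pa s
preprocess:
  poly_order: 2
  static_threshold: 0.02   # m/s
hdf:
  n_ref: 100
  ventricle: LV
phantom:
  kind: uniform_oscillation
subject:
  height_cm: 142
  weight_kg: 32
  heart_rate_bpm: 75
cohort:
  n_controls: 11
  n_patients: 21
  missing_follow_up: 5
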