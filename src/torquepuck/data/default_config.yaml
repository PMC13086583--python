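# Canonical parameter set for the confined-bacterium torque-transmission pipeline.
# All physical quantities carry explicit units in their key names
# (um, s, pN, pN um, rad). Values are the experiment-scale defaults.
seed: 0
channel:
  half_width_um: 1.0
  truncation_factor: 20.0        # truncation length L = factor * half-width
  panel_size_um: 0.25
  viscosity_pN_s_per_um2: 1.0e-3
  dead_end_um: null
bacterium:
  motor_torque_pN_um: 2.0        # flagellar-motor torque scale
  body_length_um: 5.0
  alpha: 1.5                     # dipole length / body length
  swim_speed_um_s: 20.0
puck:
  radius_um: 10.0
  rotational_diffusivity_rad2_s: 6.0e-5
  temperature_K: 298.15
bath:
  concentration_per_ml: 6.0e+8
  curvature_radius_um: 50.0
  body_length_um: 5.0
  force_pN: 0.2
  contact_time_s: 0.25
  rectification_c: 1.0
  handedness: -1
simulation:
  dt_s: 0.1
  bath_dt_s: 0.02
  duration_s: 600.0
  noise:
    diffusivity_rad2_s: 6.0e-5
    angle_measurement_sd_rad: 0.01
    position_measurement_sd_um: 0.2
inference:
  lambda: null                   # filled by the `lambda` command or user
  msad_max_lag_fraction: 0.25
  reversal_bandwidth_um: 1.0
  alpha_fit_mode: pooled
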