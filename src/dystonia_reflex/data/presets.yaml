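# Musculotendon, joint and reflex presets (SI units).
#
# Two representative parameter sets: "wrist" (hand inertia about the wrist,
# short distal muscles, long tendon path, longer neural latency) and
# "shoulder" (arm inertia about the shoulder, large proximal muscles,
# shorter latency).  Values are order-of-magnitude physiological choices
# documented in docs/methods.md; reflex gains and the default aberration
# magnitudes are calibrated so that the reference run is stable, quiet and
# returns to neutral within ~2 s of each phase end, and so that the
# aberrant-scenario battery expresses the qualitative regimes the model is
# built to study.
wrist:
  muscle:
    f_max: 100.0        # N
    l_ce_opt: 0.05      # m
    l_se_slack: 0.17    # m
    k_se_shape: 1.5
    w_fl: 0.4
    v_max: 10.0         # l_ce_opt / s
    a_hill: 0.25
    tau_act: 0.04       # s
    tau_deact: 0.06     # s
    r: 0.015            # m
  joint:
    inertia: 0.003      # kg m^2 (hand about the wrist)
    b_passive: 0.04     # N m s / rad
    theta_neutral: 0.0
  u_baseline: 0.01      # tonic resting drive to both muscles
  reflex:
    k_p: 1.6
    k_v: 0.3
    k_f: 0.25
    e_p: 0.0
    e_v: 0.0
    e_f: 0.0
    tau_p: 0.03         # s (distal latency)
    tau_v: 0.03
    tau_f: 0.03
  defaults:
    t_force: 0.3        # N m external torque, flexion-assisting
    u_vol: 0.3          # voluntary drive to the agonist
    sensitivity_magnitude: 8.0
    offset_magnitude: 0.03
    severity_magnitudes: [2.0, 4.0, 8.0]

shoulder:
  muscle:
    f_max: 500.0
    l_ce_opt: 0.10
    l_se_slack: 0.30    # long proximal tendon + aponeurosis path
    k_se_shape: 1.5
    w_fl: 0.4
    v_max: 10.0
    a_hill: 0.25
    tau_act: 0.04
    tau_deact: 0.06
    r: 0.05
  joint:
    inertia: 0.25       # kg m^2 (whole arm about the shoulder)
    b_passive: 1.5
    theta_neutral: 0.0
  u_baseline: 0.01
  reflex:
    k_p: 1.6
    k_v: 0.3
    k_f: 0.25
    e_p: 0.0
    e_v: 0.0
    e_f: 0.0
    tau_p: 0.02         # s (proximal latency, shorter than distal)
    tau_v: 0.02
    tau_f: 0.02
  defaults:
    t_force: 5.0
    u_vol: 0.3
    sensitivity_magnitude: 8.0
    offset_magnitude: 0.032
    severity_magnitudes: [2.0, 4.0, 8.0]
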