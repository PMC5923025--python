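# Demonstration study config: a three-wave assessment (baseline, ~15-month
# follow-up, re-training immediately before the third wave) whose skill-decay
# and re-training parameters are calibrated so that the provider pass rate
# (score >= 90) sits near 0.9 at baseline, near 0.5 at the follow-up, and
# near 0.9 again after re-training -- the decline-and-recovery shape of a
# yearly triage re-training study.
#
# Calibration sketch: a provider's score is approximately Binomial(100, p)
# in the common skill level p, so P(score >= 90) ~ 0.9 needs p ~ 0.93,
# ~ 0.5 needs p ~ 0.895.  With floor 0.75, p(14.6 mo) = 0.895 fixes the
# decay rate at ~0.0148 / month.
tree: asav
session_months: [0.0, 14.6, 25.1]
pool_size: 40
category_mix: {RED: 0.35, YELLOW: 0.35, GREEN: 0.25, DEAD: 0.05}
session_draw: 20
roster_size: 33
qualification_mix: {paramedic: 0.576, EMT: 0.121, other: 0.303}
employment_mix: {professional: 0.727, volunteer: 0.273}
retention: [0.667, 0.864]
skill_base_p: 0.93
qualification_offset: {paramedic: 0.003, EMT: -0.002, other: -0.008}
skill_jitter_sd: 0.015
skill_decay_rate: 0.0148
skill_floor: 0.75
retrain_gain: 0.005
retrain_before_session: 2
pass_threshold: 90.0
stop_threshold: 0.70
time_mean_s: {RED: 45.0, YELLOW: 40.0, GREEN: 20.0, DEAD: 15.0}
time_sigma: 0.35
intervention_time_s: 0.0
time_weights: {RED: 0.2, YELLOW: 0.2, GREEN: 0.6, DEAD: 0.0}
under_bias: 1.0
alpha: 0.05
seed: 17
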