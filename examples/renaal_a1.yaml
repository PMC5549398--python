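# Worked example: co-primary superiority design (approach 1) with the
# RENAAL-based planning values.  Hazards are per month; durations in months.
lambda_mc_i: 0.0074        # main component (ESRD/death), intervention
lambda_mc_c: 0.0100        # main component, control
lambda_other_i: 0.0030     # additional non-fatal composite events, intervention
lambda_other_c: 0.0045     # additional non-fatal composite events, control
recruit_months: 24.0
min_followup_months: 42.0
n_per_group: 630

approach: iut_sup_sup      # co-primary superiority (composite + main component)
alpha: 0.025               # one-sided global level
target_power: 0.90
info_fraction: 0.5
level_method: pocock
beta_l: 0.05               # admissible power loss
gamma: 0.025               # admissible wrongly-stopping rate
theta_star_hr: 1.2         # largest MC hazard ratio where stopping is 'correct'

# deviation scenarios: control-arm main-component hazard = lambda_mc_i * hr,
# composite hazard held at its planning value
scenario_hr_mc: [1.3514, 1.3, 1.25, 1.2, 1.15, 1.1, 1.05]
futility_pairs: [[0.43, 0.44], [0.5, 0.5]]
n_sims: 10000
seed: 12345
grid_step: 0.01
out_dir: results
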