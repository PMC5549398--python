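# gsfutility

Binding futility boundaries for two-stage group sequential clinical
trials with two correlated time-to-event endpoints: a composite endpoint
(CE) and its main component (MC).

## The problem

Confirmatory trials often power a composite endpoint because it accrues
events faster, while the clinically decisive question concerns the main
component alone. An interim analysis can then stop the trial early for
futility when the main component shows too little effect, even while the
composite is on track. A futility rule is a pair of p-value upper bounds
`(af_CE, af_MC)`: the trial stops at the interim when either stage-1
one-sided log-rank p-value is at or above its bound (binding rule;
efficacy stopping takes precedence). The design questions are:

* Which pairs are **admissible**, i.e. under the planning alternative
  they cost at most `beta_l` overall power *and* stop a truly effective
  trial ("wrongly") with probability at most `gamma`?
* Among those, which pair is **optimal**, i.e. maximizes the probability
  of stopping ("correctly") under a fixed deviation scenario `theta*`
  where the main-component effect is too small to be worthwhile?

This package answers both by patient-level simulation for three designs:

| approach | efficacy claim | futility monitored on |
|---|---|---|
| `iut_sup_sup` | superiority on CE **and** MC (intersection-union test) | both endpoints |
| `iut_sup_ni` | superiority on CE and non-inferiority on MC (hazard-ratio margin) | both endpoints |
| `single_ep_two_fut` | superiority on CE only | both endpoints |

## The model

Patients accrue uniformly over the recruitment period and are followed to
a common study end (recruitment + minimal follow-up); censoring is purely
administrative. Event times are exponential: the main component has
hazard `lambda_mc` per arm, additional non-fatal composite events have an
independent hazard `lambda_other` per arm, and the composite time is the
minimum of the two, so the composite is exponential with hazard
`lambda_mc + lambda_other`. The main component (it includes death) is not
censored by a preceding non-fatal event — this is what correlates the two
log-rank statistics. The interim is the calendar time at which the
expected pooled number of composite events reaches the chosen information
fraction of its study-end expectation under the planning hazards. Local
one-sided significance levels (Pocock or O'Brien–Fleming type) are
calibrated exactly through the bivariate normal distribution of the two
stage-wise log-rank statistics.

Deviation scenarios vary the control-arm main-component hazard ratio
while holding each arm's *composite* hazard at its planning value (the
non-fatal hazard compensates), so the scenarios isolate the main
component exactly.

## Worked example

The bundled configuration `examples/renaal_a1.yaml` encodes the worked
example used throughout the tests: planning hazards per month of 0.0074
(MC, intervention), 0.0100 (MC, control), 0.0030/0.0045 (additional
non-fatal events), 24 months accrual, 42 months minimal follow-up,
630 patients per group, one-sided `alpha = 0.025`, target power 0.90,
interim at half the expected composite events. These values correspond
to the published RENAAL trial in diabetic nephropathy (composite:
doubling of serum creatinine, end-stage renal disease or death; main
component: end-stage renal disease or death).

Local levels of the two-stage Pocock design:

```text
$ gsfutility levels
{
  "method": "pocock",
  "alpha1": 0.014693,
  "alpha2": 0.014693,
  "z1": 2.1783,
  "z2": 2.1783,
  "stage_correlation": 0.70710678,
  "global_level": 0.025
}
```

Operating characteristics across main-component deviation scenarios
(quick mode, 2,000 simulated trials per scenario):

```text
$ gsfutility oc examples/renaal_a1.yaml --nsims 2000 --out results
wrote 14 rows to results/oc_results.csv
```

with `results/oc_results.csv` containing, per scenario × futility pair
(columns abridged):

```text
 hr_mc  af_ep1  af_ep2  p_stop_futility_stage1  overall_power
1.3514    0.43    0.44                  0.0205         0.8780
1.2000    0.43    0.44                  0.1270         0.4355
1.1000    0.43    0.44                  0.2845         0.1570
1.0500    0.43    0.44                  0.4265         0.0570
```

The futility-stop probability rises monotonically as the main-component
hazard ratio shrinks toward 1, at every bound pair — the behaviour a
futility rule is for.

Boundary search (admissible set, frontier and optimum) in quick mode:

```text
$ gsfutility search examples/renaal_a1.yaml --nsims 2000 --out results
{
  "approach": "iut_sup_sup",
  "n_per_group": 630,
  "n_sims": 2000,
  "seed": 12345,
  "grid_step": 0.01,
  "interim_months": 34.66691206664794,
  "n_grid_pairs": 9801,
  "n_admissible": 5339,
  "n_frontier": 11,
  "n_closure_fixes": 0,
  "config_hash": "cd230dd05f09",
  "runtime_s": 4.65,
  "optimal": {
    "af_ce": 1.0,
    "af_mc": 0.36,
    "correctly_stopping_rate": 0.154,
    "wrongly_stopping_rate": 0.0245,
    "power_loss": 0.018000000000000016,
    "gamma_exhaustion": 0.98,
    "beta_l_exhaustion": 0.3600000000000003
  }
}
```

Every CSV row carries the seed and a configuration hash, so each number
is regenerable from the YAML alone. `gsfutility samplesize` computes
reference sizes (Schoenfeld closed form or simulation); the fixed-design
Schoenfeld path for the composite endpoint (hazard ratio
0.0145/0.0104 ≈ 1.394, event probabilities 0.58/0.464, power 0.90)
gives 730 patients in total.

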