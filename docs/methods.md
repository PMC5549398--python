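# Methods note

## Statistical model

### Trial and data generation

Two arms of `n_per_group` patients each. Entry times are uniform on
`[0, recruit_months]`; everyone is followed to the common study end
`recruit_months + min_followup_months`; there is no loss to follow-up,
so censoring is administrative only.

Per patient and arm, two independent exponential latent times are drawn:

* `T_mc` — the main component (MC; includes death), hazard
  `lambda_mc_{i,c}` per month;
* `T_other` — additional non-fatal composite events, hazard
  `lambda_other_{i,c}` per month.

The composite-endpoint (CE) time is `T_ce = min(T_mc, T_other)`, so the
CE is exactly exponential with hazard `lambda_mc + lambda_other`. The MC
analysis does **not** censor at a preceding non-fatal event: a patient
contributes a first composite event and, possibly later, the main
component. This within-patient sharing of `T_mc` is the only source of
correlation between the two endpoints' test statistics (observed
stage-1 normal-score correlation ≈ 0.8 at the planning hazards).

Default planning values (per month / months): `lambda_mc_i = 0.0074`,
`lambda_mc_c = 0.0100`, `lambda_other_i = 0.0030`,
`lambda_other_c = 0.0045` (hence CE hazards 0.0104 / 0.0145, CE hazard
ratio ≈ 1.394), accrual 24, minimal follow-up 42, study end 66.

### Interim timing

With uniform accrual over `[0, R]` and exponential hazard `lam`, the
expected number of events per patient by calendar time `t ≥ R` is

```
E(t) = 1 - (exp(-lam (t - R)) - exp(-lam t)) / (lam R)
```

The interim calendar time `t1` solves (by bracketed root finding)
`E_pooled(t1) = info_fraction × E_pooled(study end)` for the pooled CE
event count **under the planning hazards**; the same `t1` is reused in
deviation scenarios (as an information-rate plan would be in practice).
It does not depend on `n`. At the defaults `t1 ≈ 34.7` months.

### Tests and p-values

At each stage the one-sided log-rank statistic compares arms on data
observed by the cutoff (patients not yet recruited are excluded;
follow-up is truncated at the cutoff). `Z > 0` favours the intervention;
`p = 1 - Phi(Z)`. Stage 2 uses the full data at study end (group
sequential statistics are cumulative, not incremental). For
non-inferiority on the MC with hazard-ratio margin `m < 1` the statistic
is shifted using the Schoenfeld standard-error approximation
`SE(log HR) ≈ sqrt(4/d)` with `d` the total observed events:
`Z_ni = Z - log(m) sqrt(d)/2`. A stage with zero observed events yields
`p = 1` (no evidence).

### Local levels

For global one-sided level `alpha` and information fraction `t`, the
stage statistics are asymptotically bivariate normal with correlation
`sqrt(t)`. Local levels solve `P(Z1 > z1 or Z2 > z2) = alpha` exactly
via the bivariate normal CDF and scalar root finding: Pocock type uses
`alpha1 = alpha2` (at `alpha = 0.025`, `t = 0.5`: `alpha1 ≈ 0.0147`,
`z ≈ 2.178`); O'Brien–Fleming type uses `z1 = z2 / sqrt(t)`.

### Decision rules

Stage 1, in order of precedence:

1. **efficacy stop** — approach-specific: `iut_sup_sup` needs both
   p-values `≤ alpha1`; `iut_sup_ni` needs CE-superiority and
   MC-non-inferiority p-values `≤ alpha1`; `single_ep_two_fut` needs the
   CE p-value `≤ alpha1`;
2. **binding futility stop** — any monitored p-value `≥` its bound
   (`p1_CE ≥ af_CE` or `p1_MC ≥ af_MC`);
3. otherwise continue to stage 2, where rejection uses `alpha2` with the
   same approach-specific combination (CE only for
   `single_ep_two_fut`).

Futility bounds must exceed `alpha1` (otherwise no continuation region
exists) and a bound of 1 disables that endpoint's futility rule.

### Deviation scenarios

Scenarios index the control-arm MC hazard ratio `hr`:
`lambda_mc_c = lambda_mc_i × hr`, with each arm's **composite** hazard
held at its planning value (`lambda_other_c` compensates downward). This
keeps the CE information and effect fixed so the scenario isolates the
MC effect; a scenario with `lambda_mc_c` above the planning composite
hazard is rejected as infeasible. `hr = 1.2` is the default `theta*`
("correct to stop") scenario; the planning scenario corresponds to
`hr = 0.0100/0.0074 ≈ 1.351`.

### Admissible and optimal boundaries

On a grid of bound pairs (multiples of `grid_step` in `(alpha1, 1]`,
both axes), two stored p-value matrices — planning and `theta*`,
simulated with common random numbers and identical size — yield for each
pair: overall power and wrongly-stopping rate (planning) and
correctly-stopping rate (`theta*`). A pair is admissible when
`power ≥ target_power - beta_l` and `wrongly ≤ gamma`. Both criteria
are monotone in each bound up to Monte-Carlo noise, so the reported
admissible set is the upward closure of the raw flags (overruled cells
are counted and reported; at 10,000 replicates there are typically
none). The frontier is the set of Pareto-minimal admissible pairs. The
optimal pair maximizes the correctly-stopping rate over **all**
admissible pairs; exact ties break towards the largest `af_CE + af_MC`,
then the largest `af_CE`. An empty admissible set is a valid outcome
("no admissible boundary"), not an error.

### Sample sizes

`schoenfeld_n` implements the fixed-design Schoenfeld path: required
events `d = 4 (z_{1-alpha} + z_{power})^2 / ln(hr)^2`, total size
`d / mean(event probabilities)` rounded up to an even integer (730 at
the planning CE effect). `simulated_n` bisects on `n_per_group` until
the simulated power of the reference design (no futility stopping)
reaches the target within one Monte-Carlo standard error.

## Numerical choices

* Vectorized log-rank across simulated trials: per-trial argsort, suffix
  sums for risk sets, observed-minus-expected and hypergeometric
  variance accumulated over event times; excluded (not yet recruited)
  patients are coded with negative time and zero risk contribution.
  Agreement is tested against `lifelines` and against an exhaustive
  permutation on a 4-patient fixture.
* One seeded `numpy` generator per matrix, drawing batched arrays in a
  fixed order: results are exactly reproducible for a fixed
  `(seed, batch_size)`; the default batch is 2,000 trials.
* Common random numbers across the whole bound grid: every pair is
  evaluated on the same trials, so grid comparisons carry no
  between-pair Monte-Carlo noise, and grid evaluation is exactly equal
  to a per-pair pass through the decision rule (tested).
* Bivariate normal probabilities via `scipy.stats.multivariate_normal`;
  root finding via `brentq` on bracketed intervals.
* Experiment outputs are long-format CSV; every row carries the seed and
  a hash of all numerics-affecting configuration fields.

## Generator realism and limitations

* Exponential hazards, no loss to follow-up, no treatment switching, no
  competing-risk distinction between fatal and non-fatal events beyond
  the latent-cause construction. Real trials have non-constant hazards
  and dropout; the model is the standard planning-stage idealization.
* The non-inferiority shift uses the asymptotic Schoenfeld variance;
  at very low event counts the normal approximation is rough (stages
  with zero events are handled explicitly).
* The interim is event-driven in expectation (fixed calendar time), not
  conditional on the realized event count; realized information
  fractions therefore vary slightly across simulated trials.
* The admissibility constraints are checked on observed proportions at
  the simulation size, not on confidence bounds; at 10,000 replicates
  the Monte-Carlo standard error of a rate near 0.025 is about 0.0016.
* Known discrepancy: the exact location of the optimal pair is highly
  sensitive to the interim drift convention, because it sits where the
  wrongly-stopping rate crosses `gamma`. Published reference values for
  this worked example were produced with sample-size and statistic
  conventions that imply an interim drift a few percent lower than the
  model above; under our conventions the approach-1 search at
  `n = 630`/group returns `(1.00, 0.40)` (correct-stop rate ≈ 0.146)
  rather than `(0.43, 0.44)` (≈ 0.124), while reproducing all published
  *operating characteristics at given pairs* within ±0.02. Similarly,
  the approach-3 no-futility power at the published `n = 365`/group is
  ≈ 0.84 here, so its admissible set under `beta_l = 0.05` is empty and
  the package reports "no admissible boundary".
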