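"""Patient-level simulation of a two-arm survival trial with a composite
endpoint and its main component, and stage-wise one-sided log-rank p-values.

The composite endpoint (CE) is time to the first of several event types;
the main component (MC, typically death) is one of those types, so every MC
event is also a CE event and the two endpoint statistics are positively
correlated by construction.  Survival times are exponential (constant
hazards), accrual is uniform over the recruitment period, and censoring is
purely administrative: each patient is followed from entry until the end of
the study (recruitment period plus minimal follow-up) or until an analysis
cutoff, whichever comes first.

The latent-cause construction draws an MC time with hazard ``lambda_mc``
and an independent non-fatal event time with hazard ``lambda_other``;
the CE time is the minimum of the two, so the CE hazard is their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScenarioParams",
    "StagePValueMatrix",
    "simulate_trial",
    "expected_events",
    "interim_calendar_time",
    "logrank_pvalue",
    "simulate_pvalue_matrix",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Hazards, accrual and follow-up schedule of one simulation scenario.

    All hazards are per month; durations are months.  Allocation is 1:1.

    Parameters
    ----------
    lambda_mc_i, lambda_mc_c
        Hazard of the main-component event (e.g. death) in the
        intervention / control arm.
    lambda_other_i, lambda_other_c
        Hazard of non-fatal events that count only towards the composite.
        The implied composite hazard per arm is ``lambda_mc + lambda_other``.
    recruit_months
        Accrual duration; entry times are uniform on ``[0, recruit_months]``.
    min_followup_months
        Minimal follow-up after the last patient is recruited; the study
        ends at ``recruit_months + min_followup_months``.
    n_per_group
        Number of patients per arm.
    """

    lambda_mc_i: float
    lambda_mc_c: float
    lambda_other_i: float
    lambda_other_c: float
    recruit_months: float
    min_followup_months: float
    n_per_group: int

    def __post_init__(self) -> None:
        for name in ("lambda_mc_i", "lambda_mc_c", "lambda_other_i", "lambda_other_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lambda_mc_i + self.lambda_other_i <= 0:
            raise ValueError("intervention arm has zero total hazard")
        if self.lambda_mc_c + self.lambda_other_c <= 0:
            raise ValueError("control arm has zero total hazard")
        if self.recruit_months <= 0:
            raise ValueError("recruit_months must be positive")
        if self.min_followup_months < 0:
            raise ValueError("min_followup_months must be non-negative")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")

    @property
    def lambda_ce_i(self) -> float:
        """Composite-endpoint hazard in the intervention arm."""
        return self.lambda_mc_i + self.lambda_other_i

    @property
    def lambda_ce_c(self) -> float:
        """Composite-endpoint hazard in the control arm."""
        return self.lambda_mc_c + self.lambda_other_c

    @property
    def study_end_months(self) -> float:
        return self.recruit_months + self.min_followup_months


@dataclass
class StagePValueMatrix:
    """Stage-wise one-sided p-values for a batch of simulated trials.

    One row per simulated trial.  ``p1_*`` are interim, ``p2_*`` final
    p-values; the final statistics are cumulative (all data up to study
    end).  ``d1_ce``/``d2_ce`` count composite events at the two cutoffs.
    Trials are always simulated to completion so that any futility rule
    can be evaluated on the same matrix (common random numbers).
    """

    p1_ce: np.ndarray
    p1_mc: np.ndarray
    p2_ce: np.ndarray
    p2_mc: np.ndarray
    d1_ce: np.ndarray
    d2_ce: np.ndarray
    seed: int = 0
    scenario: str = ""
    interim_months: float = float("nan")
    n_zero_event: int = 0

    def __post_init__(self) -> None:
        for name in ("p1_ce", "p1_mc", "p2_ce", "p2_mc"):
            p = getattr(self, name)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.d1_ce > self.d2_ce):
            raise ValueError("interim CE event count exceeds final count")

    @property
    def n_sims(self) -> int:
        return len(self.p1_ce)

    def to_frame(self) -> pd.DataFrame:
        """One row per simulated trial, suitable for CSV export."""
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_sims),
                "p1_ce": self.p1_ce,
                "p1_mc": self.p1_mc,
                "p2_ce": self.p2_ce,
                "p2_mc": self.p2_mc,
                "d1_ce": self.d1_ce,
                "d2_ce": self.d2_ce,
                "seed": self.seed,
                "scenario": self.scenario,
            }
        )


def _draw_arm(
    rng: np.random.Generator, lam_mc: float, lam_other: float, n: int, shape: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Latent MC and CE times for one arm; infinite time when a hazard is 0."""
    mc = rng.exponential(1.0 / lam_mc, shape) if lam_mc > 0 else np.full(shape, np.inf)
    other = (
        rng.exponential(1.0 / lam_other, shape) if lam_other > 0 else np.full(shape, np.inf)
    )
    return mc, np.minimum(mc, other)


def _simulate_arrays(
    params: ScenarioParams, n_sims: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorised patient data for ``n_sims`` trials.

    Returns arrays of shape ``(n_sims, 2 * n_per_group)`` with the control
    arm in the first ``n_per_group`` columns.  Draw order is fixed, so the
    result is reproducible for a fixed generator state.
    """
    n = params.n_per_group
    shape = (n_sims, n)
    entry_c = rng.uniform(0.0, params.recruit_months, shape)
    mc_c, ce_c = _draw_arm(rng, params.lambda_mc_c, params.lambda_other_c, n, shape)
    entry_i = rng.uniform(0.0, params.recruit_months, shape)
    mc_i, ce_i = _draw_arm(rng, params.lambda_mc_i, params.lambda_other_i, n, shape)
    return {
        "entry": np.concatenate([entry_c, entry_i], axis=1),
        "mc": np.concatenate([mc_c, mc_i], axis=1),
        "ce": np.concatenate([ce_c, ce_i], axis=1),
        "is_control": np.concatenate(
            [np.ones(n, dtype=bool), np.zeros(n, dtype=bool)]
        ),
    }


def simulate_trial(params: ScenarioParams, seed: int) -> pd.DataFrame:
    """Simulate one trial; returns a patient table.

    Columns: ``arm`` ('control'/'intervention'), ``entry_time`` (months
    since study start), ``mc_time`` and ``ce_time`` (latent months from
    entry to the main-component / first composite event; ``ce_time <=
    mc_time`` always), and ``admin_censor_time`` (months from entry to
    administrative censoring at study end).
    """
    rng = np.random.default_rng(seed)
    arrays = _simulate_arrays(params, 1, rng)
    arm = np.where(arrays["is_control"], "control", "intervention")
    entry = arrays["entry"][0]
    return pd.DataFrame(
        {
            "arm": arm,
            "entry_time": entry,
            "mc_time": arrays["mc"][0],
            "ce_time": arrays["ce"][0],
            "admin_censor_time": params.study_end_months - entry,
        }
    )


def expected_events(lam: float, t: float, recruit_months: float) -> float:
    """Expected fraction of patients with an event by calendar time ``t``.

    Entry is uniform on ``[0, recruit_months]`` and the event time is
    exponential with hazard ``lam``; events are counted while the patient
    is on study (no loss to follow-up other than the cutoff).
    """
    if t <= 0 or lam <= 0:
        return 0.0
    a = min(t, recruit_months)
    # (1/R) * int_0^a 1 - exp(-lam (t - e)) de
    return (a - (np.exp(-lam * (t - a)) - np.exp(-lam * t)) / lam) / recruit_months


def _expected_ce_events(params: ScenarioParams, t: float) -> float:
    n = params.n_per_group
    return n * (
        expected_events(params.lambda_ce_c, t, params.recruit_months)
        + expected_events(params.lambda_ce_i, t, params.recruit_months)
    )


def interim_calendar_time(params: ScenarioParams, info_fraction: float) -> float:
    """Calendar time (months) at which the expected pooled composite-event
    count reaches ``info_fraction`` of its value at study end.

    The expectation is taken under the hazards in ``params`` (planning
    values), with uniform staggered entry and administrative censoring.
    Monotone increasing in ``info_fraction``.
    """
    if not 0.0 < info_fraction <= 1.0:
        raise ValueError("info_fraction must lie in (0, 1]")
    t_end = params.study_end_months
    if info_fraction == 1.0:
        return t_end
    target = info_fraction * _expected_ce_events(params, t_end)
    return float(
        optimize.brentq(
            lambda t: _expected_ce_events(params, t) - target, 1e-9, t_end, xtol=1e-10
        )
    )


def _logrank_z(
    time: np.ndarray,
    event: np.ndarray,
    is_control: np.ndarray,
    margin_hr: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-sided log-rank statistic over a batch of trials.

    ``time``/``event`` have shape ``(n_trials, n_patients)``; excluded
    patients (not yet entered at the cutoff) carry a negative time and no
    event, which removes them from every risk set.  Returns ``(z, d)``
    where positive ``z`` favours the intervention (control hazard larger)
    and ``d`` is the total event count.  For ``margin_hr < 1`` the
    statistic is shifted on the log hazard-ratio scale by
    ``-log(margin_hr) / SE`` with the Schoenfeld approximation
    ``SE(log HR) = sqrt(4 / d)``, i.e. a non-inferiority test of
    ``H0: log(lambda_C / lambda_I) <= log(margin_hr)``; at ``margin_hr = 1``
    it reduces exactly to the standard log-rank statistic.

    Trials with no events get ``z = -inf`` (p-value 1 downstream).
    """
    order = np.argsort(time, axis=1, kind="stable")
    ev = np.take_along_axis(event, order, axis=1)
    ctl = np.take_along_axis(np.broadcast_to(is_control, time.shape), order, axis=1)
    n_pat = time.shape[1]
    at_risk = (n_pat - np.arange(n_pat)).astype(float)
    # excluded patients sort first (negative times) and must not count
    excluded = np.take_along_axis(time < 0, order, axis=1)
    n_excluded_before = np.cumsum(excluded, axis=1)
    at_risk = at_risk[None, :] - (n_excluded_before.sum(axis=1, keepdims=True) - n_excluded_before)
    ctl_cum = np.cumsum(ctl & ~excluded, axis=1)
    n_ctl_risk = ctl_cum[:, -1:] - (ctl_cum - (ctl & ~excluded))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ctl = np.where(at_risk > 0, n_ctl_risk / at_risk, 0.0)
    o_minus_e = np.where(ev, ctl - p_ctl, 0.0).sum(axis=1)
    var = np.where(ev, p_ctl * (1.0 - p_ctl), 0.0).sum(axis=1)
    d = ev.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, o_minus_e / np.sqrt(np.maximum(var, 1e-300)), -np.inf)
    if margin_hr != 1.0:
        if not 0.0 < margin_hr <= 1.0:
            raise ValueError("margin_hr must lie in (0, 1]")
        shift = -np.log(margin_hr) * np.sqrt(np.maximum(d, 0)) / 2.0
        z = np.where(d > 0, z + shift, z)
    return z, d


def _observed_at_cutoff(
    entry: np.ndarray, latent: np.ndarray, cutoff: float, study_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (time-on-study, event) pairs at a calendar cutoff.

    Follow-up per patient is ``min(latent event time, study_end - entry,
    cutoff - entry)``; patients entering after the cutoff are flagged with
    time -1 and excluded from the analysis.
    """
    horizon = np.minimum(cutoff, study_end) - entry
    event = latent <= horizon
    time = np.minimum(latent, horizon)
    not_entered = horizon <= 0
    time = np.where(not_entered, -1.0, time)
    event &= ~not_entered
    return time, event


def logrank_pvalue(
    patients: pd.DataFrame,
    cutoff_months: float,
    endpoint: str,
    margin_hr: float = 1.0,
) -> tuple[float, int]:
    """One-sided log-rank p-value and event count at a calendar cutoff.

    ``endpoint`` is ``"ce"`` or ``"mc"``.  For the main component a prior
    non-fatal composite event does **not** censor: follow-up for death
    continues to the cutoff.  The alternative is "control hazard larger
    than intervention hazard"; for ``margin_hr < 1`` the hypothesis is
    non-inferiority with that hazard-ratio margin (see :func:`_logrank_z`).

    Raises ``ValueError`` when no events are observed in either arm.
    """
    if endpoint not in ("ce", "mc"):
        raise ValueError("endpoint must be 'ce' or 'mc'")
    latent = patients[f"{endpoint}_time"].to_numpy(float)[None, :]
    entry = patients["entry_time"].to_numpy(float)[None, :]
    study_end = (patients["entry_time"] + patients["admin_censor_time"]).max()
    time, event = _observed_at_cutoff(entry, latent, cutoff_months, study_end)
    if not event.any():
        raise ValueError("no events observed in either arm at this cutoff")
    is_control = (patients["arm"] == "control").to_numpy()
    z, d = _logrank_z(time, event, is_control, margin_hr=margin_hr)
    return float(stats.norm.sf(z[0])), int(d[0])


def simulate_pvalue_matrix(
    params: ScenarioParams,
    n_sims: int,
    seed: int,
    info_fraction: float = 0.5,
    mc_margin_hr: float = 1.0,
    interim_months: float | None = None,
    scenario: str = "",
    batch_size: int = 2000,
) -> StagePValueMatrix:
    """Simulate ``n_sims`` trials and collect stage-wise one-sided p-values.

    The interim cutoff is ``interim_months`` when given (e.g. the calendar
    time derived from the *planning* hazards when ``params`` describes a
    deviation scenario), otherwise it is computed from ``params`` via
    :func:`interim_calendar_time`.  ``mc_margin_hr`` applies a
    non-inferiority margin to the main-component tests (both stages), as
    used when that endpoint is tested for non-inferiority.

    Trials with zero events for an endpoint at a stage get p = 1 there
    (cannot reject; will trigger futility); their count is recorded in
    ``n_zero_event``.  Simulation is batched to bound memory; results are
    reproducible for a fixed ``(seed, batch_size)``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    if interim_months is None:
        interim_months = interim_calendar_time(params, info_fraction)
    t_end = params.study_end_months
    if not 0.0 < interim_months <= t_end:
        raise ValueError("interim cutoff outside the study period")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols = {k: [] for k in ("p1_ce", "p1_mc", "p2_ce", "p2_mc", "d1_ce", "d2_ce")}
    n_zero = 0
    done = 0
    while done < n_sims:
        m = min(batch_size, n_sims - done)
        arrays = _simulate_arrays(params, m, rng)
        is_control = arrays["is_control"]
        for stage, cutoff in ((1, interim_months), (2, t_end)):
            for ep in ("ce", "mc"):
                time, event = _observed_at_cutoff(
                    arrays["entry"], arrays[ep], cutoff, t_end
                )
                margin = mc_margin_hr if ep == "mc" else 1.0
                z, d = _logrank_z(time, event, is_control, margin_hr=margin)
                p = np.where(np.isfinite(z), stats.norm.sf(z), 1.0)
                n_zero += int(np.sum(d == 0))
                cols[f"p{stage}_{ep}"].append(p)
                if ep == "ce":
                    cols[f"d{stage}_ce"].append(d)
        done += m

    return StagePValueMatrix(
        p1_ce=np.concatenate(cols["p1_ce"]),
        p1_mc=np.concatenate(cols["p1_mc"]),
        p2_ce=np.concatenate(cols["p2_ce"]),
        p2_mc=np.concatenate(cols["p2_mc"]),
        d1_ce=np.concatenate(cols["d1_ce"]),
        d2_ce=np.concatenate(cols["d2_ce"]),
        seed=seed,
        scenario=scenario,
        interim_months=float(interim_months),
        n_zero_event=n_zero,
    )
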