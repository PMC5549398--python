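"""Reference-design sample sizes (no futility stopping), by the Schoenfeld
closed form for a fixed design and by simulation for the group sequential
two-endpoint designs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil, log

import numpy as np
from scipy import stats

from .designs import DesignSpec, FutilityPair
from .gsd_levels import local_levels
from .oc_engine import operating_characteristics
from .trial_model import ScenarioParams, simulate_pvalue_matrix

__all__ = ["SampleSizeResult", "schoenfeld_n", "simulated_n"]


@dataclass(frozen=True)
class SampleSizeResult:
    n_total: int
    n_per_group: int
    method: str  # schoenfeld_fixed | simulation_gsd
    achieved_power: float = np.nan
    power_se: float = np.nan
    n_events: float = np.nan
    search_path: tuple = ()

    def __post_init__(self) -> None:
        if self.n_total != 2 * self.n_per_group:
            raise ValueError("n_total must equal 2 * n_per_group")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")


def schoenfeld_n(
    hr: float,
    alpha: float,
    power: float,
    p_event_c: float,
    p_event_i: float,
) -> SampleSizeResult:
    """Fixed-design sample size for a one-sided log-rank test.

    Required events ``d = 4 (z_{1-alpha} + z_{power})^2 / ln(hr)^2``
    (Schoenfeld, 1:1 allocation); the total sample size is ``d`` divided
    by the average event probability, rounded up to an even integer.
    ``hr`` is the control/intervention hazard ratio and must exceed 1
    (the powered direction).
    """
    if hr <= 1.0:
        raise ValueError("hr must exceed 1")
    for p in (p_event_c, p_event_i):
        if not 0.0 < p < 1.0:
            raise ValueError("event probabilities must lie in (0, 1)")
    z = stats.norm.isf(alpha) + stats.norm.isf(1.0 - power)
    d = 4.0 * z**2 / log(hr) ** 2
    n_total = ceil(d / ((p_event_c + p_event_i) / 2.0))
    n_total += n_total % 2
    return SampleSizeResult(
        n_total=n_total, n_per_group=n_total // 2, method="schoenfeld_fixed", n_events=d
    )


def simulated_n(
    spec: DesignSpec,
    params: ScenarioParams,
    target_power: float,
    n_sims: int,
    seed: int,
    n_range: tuple[int, int] = (50, 2000),
) -> SampleSizeResult:
    """Smallest per-group size whose simulated reference-design power
    reaches the target.

    The reference design is the group sequential design without futility
    stopping (both bounds at 1).  Power is estimated by simulation at each
    candidate ``n`` (``params`` supplies hazards and schedule; its
    ``n_per_group`` is overridden), and a bisection on ``n`` returns the
    smallest size whose estimate is within one Monte-Carlo standard error
    of the target or above it.
    """
    if not 0.5 < target_power < 1.0:
        raise ValueError("target_power must lie in (0.5, 1)")
    levels = local_levels(spec.alpha, spec.info_fraction, spec.level_method)
    fut = FutilityPair(1.0, 1.0)
    path: list[tuple[int, float]] = []

    def power_at(n: int) -> float:
        p = replace(params, n_per_group=n)
        matrix = simulate_pvalue_matrix(
            p, n_sims=n_sims, seed=seed, info_fraction=spec.info_fraction,
            mc_margin_hr=spec.mc_margin_hr,
        )
        oc = operating_characteristics(matrix, spec, levels, fut)
        path.append((n, oc.overall_power))
        return oc.overall_power

    lo, hi = n_range
    se = np.sqrt(target_power * (1.0 - target_power) / n_sims)
    p_lo, p_hi = power_at(lo), power_at(hi)
    if not (p_lo < target_power <= p_hi + se):
        raise ValueError(
            f"search range does not bracket the target power "
            f"(power {p_lo:.3f} at n={lo}, {p_hi:.3f} at n={hi})"
        )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power - se:
            hi = mid
        else:
            lo = mid
    achieved = power_at(hi)
    return SampleSizeResult(
        n_total=2 * hi,
        n_per_group=hi,
        method="simulation_gsd",
        achieved_power=achieved,
        power_se=float(np.sqrt(achieved * (1 - achieved) / n_sims)),
        search_path=tuple(path),
    )
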