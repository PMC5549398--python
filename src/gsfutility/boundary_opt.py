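"""Grid search for admissible and optimal binding futility boundary pairs.

A futility pair (af_CE, af_MC) is *admissible* for tolerances (beta_l,
gamma) when, under the planning alternative, (i) the overall power of the
design with that binding futility rule is at least target_power - beta_l
and (ii) the probability of stopping for futility at the interim (the
'wrongly' stopping rate) is at most gamma.  Among admissible pairs, the
*optimal* pair maximizes the probability of stopping for futility under
the theta* scenario (the 'correctly' stopping rate).

Both alternatives are evaluated on stored p-value matrices simulated once
with common random numbers, so every grid pair is compared on the same
trials and the ranking is free of between-pair Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import DesignSpec, FutilityPair, apply_design_batch
from .gsd_levels import LocalLevels
from .trial_model import StagePValueMatrix

__all__ = ["AdmissibleFrontier", "futility_grid", "admissible_set", "optimal_pair"]


@dataclass
class AdmissibleFrontier:
    """Evaluated futility grid with admissibility flags and (optionally)
    the optimal pair.

    ``grid_ep1``/``grid_ep2`` are the axis values; the 2-D arrays are
    indexed ``[i, j]`` for pair ``(grid_ep1[i], grid_ep2[j])``.
    ``admissible`` is the monotone (upward) closure of the raw per-pair
    criterion; cells where closure overruled the raw flag are counted in
    ``n_closure_fixes``.  ``frontier`` marks Pareto-minimal admissible
    pairs (no other admissible pair is as small or smaller in both
    components); these trace the lower staircase of the admissible
    region.
    """

    grid_step: float
    grid_ep1: np.ndarray
    grid_ep2: np.ndarray
    power_h1: np.ndarray
    wrongly_rate: np.ndarray
    correctly_rate: np.ndarray
    admissible: np.ndarray
    frontier: np.ndarray
    n_closure_fixes: int
    beta_l: float
    gamma: float
    target_power: float
    optimal: FutilityPair | None = None
    optimal_correct_rate: float = np.nan

    @property
    def n_admissible(self) -> int:
        return int(self.admissible.sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per evaluated pair (the content of the frontier plot)."""
        i, j = np.meshgrid(
            np.arange(len(self.grid_ep1)), np.arange(len(self.grid_ep2)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "af_ep1": self.grid_ep1[i.ravel()],
                "af_ep2": self.grid_ep2[j.ravel()],
                "power_h1": self.power_h1.ravel(),
                "power_loss": self.target_power - self.power_h1.ravel(),
                "wrongly_rate": self.wrongly_rate.ravel(),
                "correctly_rate": self.correctly_rate.ravel(),
                "admissible": self.admissible.ravel(),
                "frontier": self.frontier.ravel(),
            }
        )


def futility_grid(levels: LocalLevels, grid_step: float) -> np.ndarray:
    """Futility-bound grid: multiples of ``grid_step`` in (alpha1, 1]."""
    if not 0.0 < grid_step < 1.0:
        raise ValueError("grid_step must lie in (0, 1)")
    n_dec = max(0, int(np.ceil(-np.log10(grid_step))))
    vals = np.round(np.arange(grid_step, 1.0 + grid_step / 2, grid_step), n_dec + 2)
    return vals[(vals > levels.alpha1) & (vals <= 1.0)]


def _evaluate_grid(
    matrix: StagePValueMatrix,
    spec: DesignSpec,
    levels: LocalLevels,
    grid1: np.ndarray,
    grid2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Futility-stop rate and overall power for every grid pair.

    Vectorised over the second grid axis; the stage-1 efficacy mask and
    the final-analysis rejection mask do not depend on the futility pair,
    so they are computed once.
    """
    base = apply_design_batch(
        matrix.p1_ce, matrix.p1_mc, matrix.p2_ce, matrix.p2_mc,
        levels, FutilityPair(1.0, 1.0), spec,
    )
    eff = base["stop_efficacy"]
    final_reject = base["reject"] & ~eff  # continued-and-rejected, before futility
    n = matrix.n_sims
    p_fut = np.empty((len(grid1), len(grid2)))
    power = np.empty_like(p_fut)
    hit2 = matrix.p1_mc[:, None] >= grid2[None, :]  # (n_sims, G2)
    for i, a1 in enumerate(grid1):
        futile = ((matrix.p1_ce >= a1)[:, None] | hit2) & ~eff[:, None]
        p_fut[i] = futile.sum(axis=0) / n
        power[i] = (eff.sum() + (final_reject[:, None] & ~futile).sum(axis=0)) / n
    return p_fut, power


def _upward_closure(raw: np.ndarray) -> np.ndarray:
    """A cell is admissible when it or any component-wise smaller cell is."""
    closed = np.logical_or.accumulate(raw, axis=0)
    return np.logical_or.accumulate(closed, axis=1)


def admissible_set(
    matrix_h1: StagePValueMatrix,
    matrix_thetastar: StagePValueMatrix,
    spec: DesignSpec,
    levels: LocalLevels,
    grid_step: float = 0.01,
) -> AdmissibleFrontier:
    """Evaluate the full futility-pair grid and flag admissible pairs.

    ``matrix_h1`` is simulated under the planning alternative and supplies
    both the power-loss criterion and the 'wrongly' stopping rate;
    ``matrix_thetastar`` supplies the 'correctly' stopping rate.  The two
    matrices must share the simulation size (common random numbers).

    The raw admissibility criterion is monotone in each bound apart from
    Monte-Carlo noise; the returned flags are its upward closure, with the
    number of overruled cells recorded.
    """
    if matrix_h1.n_sims != matrix_thetastar.n_sims:
        raise ValueError("matrices must share n_sims (common random numbers)")
    grid1 = futility_grid(levels, grid_step)
    grid2 = futility_grid(levels, grid_step)
    wrongly, power_h1 = _evaluate_grid(matrix_h1, spec, levels, grid1, grid2)
    correctly, _ = _evaluate_grid(matrix_thetastar, spec, levels, grid1, grid2)

    raw = (power_h1 >= spec.target_power - spec.beta_l - 1e-12) & (
        wrongly <= spec.gamma + 1e-12
    )
    admissible = _upward_closure(raw)
    n_fixes = int((admissible & ~raw).sum())

    # frontier: Pareto-minimal admissible cells (no other admissible cell
    # <= in both axes); with an up-closed set it suffices to look at the
    # two immediate lower neighbours
    dominated = np.zeros_like(admissible)
    dominated[1:, :] |= admissible[:-1, :]
    dominated[:, 1:] |= admissible[:, :-1]
    frontier = admissible & ~dominated

    return AdmissibleFrontier(
        grid_step=grid_step,
        grid_ep1=grid1,
        grid_ep2=grid2,
        power_h1=power_h1,
        wrongly_rate=wrongly,
        correctly_rate=correctly,
        admissible=admissible,
        frontier=frontier,
        n_closure_fixes=n_fixes,
        beta_l=spec.beta_l,
        gamma=spec.gamma,
        target_power=spec.target_power,
    )


def optimal_pair(frontier: AdmissibleFrontier) -> AdmissibleFrontier:
    """Select the admissible pair maximizing the correctly-stopping rate.

    The search runs over all admissible pairs; the correctly-stopping rate
    is non-increasing in each bound, so the maximum is always attained on
    or adjacent to the frontier.  Exact ties (identical stop counts) are
    broken towards the largest ``af_ep1 + af_ep2`` — the least aggressive
    rule among equals — then the largest ``af_ep1``.

    With no admissible pair, ``optimal`` stays ``None`` (a valid outcome:
    no boundary meets the tolerances), not an error.
    """
    if not frontier.admissible.any():
        frontier.optimal = None
        frontier.optimal_correct_rate = np.nan
        return frontier
    rates = np.where(frontier.admissible, frontier.correctly_rate, -np.inf)
    best = rates.max()
    cand = rates >= best - 1e-12
    ii, jj = np.nonzero(cand)
    a1 = frontier.grid_ep1[ii]
    a2 = frontier.grid_ep2[jj]
    order = np.lexsort((-a1, -(a1 + a2)))
    k = order[0]
    frontier.optimal = FutilityPair(float(a1[k]), float(a2[k]))
    frontier.optimal_correct_rate = float(frontier.correctly_rate[ii[k], jj[k]])
    return frontier
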