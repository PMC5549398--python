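"""Monte-Carlo operating characteristics of a (design, futility pair) on a
simulated p-value matrix, and the correctly/wrongly-stopping classification.

'Wrongly' stopping for futility is the futility-stop probability when the
planning assumptions hold (the trial should have continued); 'correctly'
stopping is the same probability under the theta* scenario, the largest
effect for which an early stop is still considered the right call.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignSpec, FutilityPair, apply_design_batch
from .gsd_levels import LocalLevels
from .trial_model import StagePValueMatrix

__all__ = ["OCResult", "operating_characteristics", "classify_rates"]


@dataclass(frozen=True)
class OCResult:
    """Empirical operating characteristics with Monte-Carlo standard errors.

    ``power_loss`` is the anticipated power (design target, e.g. 0.90)
    minus the observed overall power; ``no_futility_power`` is the power
    of the same design on the same matrix with both futility bounds at 1,
    reported alongside for reference.  ``corr_ep_stage1``/``corr_ep_stage2``
    are empirical correlations of the two endpoints' normal scores
    ``Phi^{-1}(1 - p)`` at each stage.
    """

    p_stop_efficacy_stage1: float
    p_stop_futility_stage1: float
    p_continue: float
    overall_power: float
    power_loss: float
    no_futility_power: float
    corr_ep_stage1: float
    corr_ep_stage2: float
    n_sims: int
    se_futility: float
    se_power: float
    scenario: str = ""
    approach: str = ""
    af_ep1: float = np.nan
    af_ep2: float = np.nan
    seed: int = 0

    def to_row(self) -> dict:
        return asdict(self)


def _normal_score_corr(p_a: np.ndarray, p_b: np.ndarray) -> float:
    za = stats.norm.isf(np.clip(p_a, 1e-12, 1 - 1e-12))
    zb = stats.norm.isf(np.clip(p_b, 1e-12, 1 - 1e-12))
    return float(np.corrcoef(za, zb)[0, 1])


def operating_characteristics(
    matrix: StagePValueMatrix,
    spec: DesignSpec,
    levels: LocalLevels,
    fut: FutilityPair,
) -> OCResult:
    """Apply the design's decision rule to every simulated trial.

    Stage-1 proportions are exact on counts (they sum to 1); the overall
    power counts stage-1 efficacy stops plus continued trials that reject
    at the final analysis.
    """
    n = matrix.n_sims
    if n == 0:
        raise ValueError("empty p-value matrix")
    masks = apply_design_batch(
        matrix.p1_ce, matrix.p1_mc, matrix.p2_ce, matrix.p2_mc, levels, fut, spec
    )
    reference = apply_design_batch(
        matrix.p1_ce, matrix.p1_mc, matrix.p2_ce, matrix.p2_mc,
        levels, FutilityPair(1.0, 1.0), spec,
    )
    p_eff = masks["stop_efficacy"].sum() / n
    p_fut = masks["stop_futility"].sum() / n
    power = masks["reject"].sum() / n
    return OCResult(
        p_stop_efficacy_stage1=p_eff,
        p_stop_futility_stage1=p_fut,
        p_continue=1.0 - p_eff - p_fut,
        overall_power=power,
        power_loss=spec.target_power - power,
        no_futility_power=reference["reject"].sum() / n,
        corr_ep_stage1=_normal_score_corr(matrix.p1_ce, matrix.p1_mc),
        corr_ep_stage2=_normal_score_corr(matrix.p2_ce, matrix.p2_mc),
        n_sims=n,
        se_futility=float(np.sqrt(p_fut * (1 - p_fut) / n)),
        se_power=float(np.sqrt(power * (1 - power) / n)),
        scenario=matrix.scenario,
        approach=spec.approach.value,
        af_ep1=fut.af_ep1,
        af_ep2=fut.af_ep2,
        seed=matrix.seed,
    )


def classify_rates(oc_planning: OCResult, oc_thetastar: OCResult) -> tuple[float, float]:
    """(wrongly, correctly) stopping-for-futility rates.

    ``oc_planning`` must be computed under the planning alternative and
    ``oc_thetastar`` under the theta* scenario, with identical design and
    futility pair (checked on metadata).
    """
    if (oc_planning.approach, oc_planning.af_ep1, oc_planning.af_ep2) != (
        oc_thetastar.approach,
        oc_thetastar.af_ep1,
        oc_thetastar.af_ep2,
    ):
        raise ValueError("operating characteristics use different designs or futility pairs")
    return oc_planning.p_stop_futility_stage1, oc_thetastar.p_stop_futility_stage1


def oc_table(results: list[OCResult]) -> pd.DataFrame:
    """Long-format table, one row per (scenario, futility pair, design)."""
    return pd.DataFrame([r.to_row() for r in results])
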