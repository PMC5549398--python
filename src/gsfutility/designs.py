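"""Stage-wise decision rules of the three two-endpoint group sequential
designs, applied to one-sided stage p-values.

Endpoint 1 is the composite endpoint (CE), endpoint 2 the main component
(MC) throughout.

* ``IUT_SUP_SUP`` (Approach 1): both endpoints are co-primary and tested
  for superiority under the intersection-union principle; every rejection
  requires both p-values below their local level.
* ``IUT_SUP_NI`` (Approach 2): as above, but the main component is tested
  for non-inferiority with a hazard-ratio margin below 1.
* ``SINGLE_EP_TWO_FUT`` (Approach 3): efficacy is claimed on the composite
  endpoint alone; the main component only contributes an additional
  binding futility criterion at the interim.

In all three designs the trial stops for futility at stage 1 when either
interim p-value reaches its futility bound; the rule is binding.  Efficacy
is evaluated before futility, which only matters for ``SINGLE_EP_TWO_FUT``
where the two stage-1 regions can overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .gsd_levels import LocalLevels

__all__ = ["Approach", "DesignSpec", "FutilityPair", "TrialOutcome", "apply_design", "apply_design_batch"]


class Approach(str, Enum):
    IUT_SUP_SUP = "iut_sup_sup"
    IUT_SUP_NI = "iut_sup_ni"
    SINGLE_EP_TWO_FUT = "single_ep_two_fut"


@dataclass(frozen=True)
class DesignSpec:
    """Design-level configuration shared across modules.

    ``theta_star_hr`` is the largest main-component hazard ratio under the
    alternative for which a futility stop is still considered correct;
    ``beta_l`` and ``gamma`` bound the admissible power loss and the
    admissible 'wrongly' stopping rate used by the boundary search.
    """

    approach: Approach
    alpha: float = 0.025
    target_power: float = 0.90
    info_fraction: float = 0.5
    level_method: str = "pocock"
    ni_margin_hr: float = 1.0
    beta_l: float = 0.05
    gamma: float = 0.025
    theta_star_hr: float = 1.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "approach", Approach(self.approach))
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0.5 < self.target_power < 1.0:
            raise ValueError("target_power must lie in (0.5, 1)")
        if not 0.0 < self.info_fraction < 1.0:
            raise ValueError("info_fraction must lie in (0, 1)")
        if not 0.0 < self.ni_margin_hr <= 1.0:
            raise ValueError("ni_margin_hr must lie in (0, 1]")
        if self.approach is Approach.IUT_SUP_NI and self.ni_margin_hr >= 1.0:
            raise ValueError("IUT_SUP_NI requires a non-inferiority margin below 1")
        for name in ("beta_l", "gamma"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.theta_star_hr <= 1.0:
            raise ValueError("theta_star_hr must exceed 1")

    @property
    def mc_margin_hr(self) -> float:
        """Margin applied to the main-component tests (1 = superiority)."""
        return self.ni_margin_hr if self.approach is Approach.IUT_SUP_NI else 1.0


@dataclass(frozen=True)
class FutilityPair:
    """Interim p-value futility bounds for (composite, main component)."""

    af_ep1: float
    af_ep2: float

    def __post_init__(self) -> None:
        for v in (self.af_ep1, self.af_ep2):
            if not 0.0 < v <= 1.0:
                raise ValueError("futility bounds must lie in (0, 1]")

    def validate_against(self, levels: LocalLevels) -> None:
        if self.af_ep1 <= levels.alpha1 or self.af_ep2 <= levels.alpha1:
            raise ValueError("futility bound must exceed alpha1 (empty continuation region)")


@dataclass(frozen=True)
class TrialOutcome:
    """Stage-1 decision and, for continued trials, the final decision."""

    stage1: str  # STOP_EFFICACY | STOP_FUTILITY | CONTINUE
    final: str  # REJECT | ACCEPT | NA

    def __post_init__(self) -> None:
        if self.stage1 not in ("STOP_EFFICACY", "STOP_FUTILITY", "CONTINUE"):
            raise ValueError(f"unknown stage-1 decision {self.stage1!r}")
        if self.stage1 == "CONTINUE" and self.final not in ("REJECT", "ACCEPT"):
            raise ValueError("continued trials need a final REJECT/ACCEPT decision")
        if self.stage1 != "CONTINUE" and self.final != "NA":
            raise ValueError("stopped trials have no final-analysis decision")

    @property
    def rejected(self) -> bool:
        return self.stage1 == "STOP_EFFICACY" or self.final == "REJECT"


def apply_design_batch(
    p1_ep1: np.ndarray,
    p1_ep2: np.ndarray,
    p2_ep1: np.ndarray,
    p2_ep2: np.ndarray,
    levels: LocalLevels,
    fut: FutilityPair,
    spec: DesignSpec,
) -> dict[str, np.ndarray]:
    """Vectorised decision rule over arrays of trials.

    Returns boolean masks ``stop_efficacy``, ``stop_futility``,
    ``continue_``, ``reject`` (overall rejection).  Boundary conventions:
    efficacy uses <=, futility uses >=.
    """
    for p in (p1_ep1, p1_ep2, p2_ep1, p2_ep2):
        if np.any((np.asarray(p) < 0) | (np.asarray(p) > 1)):
            raise ValueError("p-values must lie in [0, 1]")
    fut.validate_against(levels)
    a1, a2 = levels.alpha1, levels.alpha2
    iut = spec.approach in (Approach.IUT_SUP_SUP, Approach.IUT_SUP_NI)
    if iut:
        eff = (p1_ep1 <= a1) & (p1_ep2 <= a1)
        final_reject = (p2_ep1 <= a2) & (p2_ep2 <= a2)
    else:
        eff = p1_ep1 <= a1
        final_reject = p2_ep1 <= a2
    futile = ((p1_ep1 >= fut.af_ep1) | (p1_ep2 >= fut.af_ep2)) & ~eff
    cont = ~eff & ~futile
    return {
        "stop_efficacy": eff,
        "stop_futility": futile,
        "continue_": cont,
        "reject": eff | (cont & final_reject),
    }


def apply_design(
    p: dict[str, float],
    levels: LocalLevels,
    fut: FutilityPair,
    spec: DesignSpec,
) -> TrialOutcome:
    """Decision for one trial from its stage-wise one-sided p-values.

    ``p`` has keys ``p1_ep1``, ``p1_ep2``, ``p2_ep1``, ``p2_ep2`` (the
    stage-2 values are ignored when the trial stops at stage 1).
    """
    masks = apply_design_batch(
        np.array([p["p1_ep1"]]),
        np.array([p["p1_ep2"]]),
        np.array([p.get("p2_ep1", 1.0)]),
        np.array([p.get("p2_ep2", 1.0)]),
        levels,
        fut,
        spec,
    )
    if masks["stop_efficacy"][0]:
        return TrialOutcome("STOP_EFFICACY", "NA")
    if masks["stop_futility"][0]:
        return TrialOutcome("STOP_FUTILITY", "NA")
    return TrialOutcome("CONTINUE", "REJECT" if masks["reject"][0] else "ACCEPT")
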