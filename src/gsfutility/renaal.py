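"""Planning assumptions of the RENAAL-based worked example.

RENAAL was a randomized placebo-controlled trial of losartan in type 2
diabetes with nephropathy whose primary outcome was a composite of
doubling of serum creatinine, end-stage renal disease and death; death is
the clinically most relevant component.  The planning 5-year event rates
of 0.58 (control) and 0.464 (intervention) translate, under constant
hazards, into monthly composite hazards 0.0145 and 0.0104; the assumed
main-component (death) hazards are 0.0100 and 0.0074, so the non-fatal
event hazards are the differences, 0.0045 and 0.0030 per month.  Accrual
ran over 2 years with a minimal follow-up of 3.5 years, 1:1 allocation.

Deviation scenarios vary only the main-component assumption: control
hazard ratios {planning (~1.351), 1.3, 1.25, 1.2, 1.15, 1.1, 1.05} with
the intervention hazard fixed at 0.0074.  The composite-endpoint hazards
stay at their planning values (the deviation is confined to the main
component), so the non-fatal event hazard is the difference
``lambda_ce - lambda_mc`` per arm in every scenario.  A hazard ratio of
1.2 (scenario 4) is treated as the largest effect for which a futility
stop is still 'correct'.
"""

from __future__ import annotations

from dataclasses import replace

from .designs import Approach, DesignSpec
from .trial_model import ScenarioParams

__all__ = [
    "PLANNING_PARAMS",
    "SCENARIO_HRS",
    "N_PER_GROUP",
    "OPTIMAL_PAIRS",
    "planning_params",
    "scenario_params",
    "design_spec",
]

LAMBDA_MC_I = 0.0074
LAMBDA_MC_C = 0.0100
LAMBDA_OTHER_I = 0.0030
LAMBDA_OTHER_C = 0.0045
RECRUIT_MONTHS = 24.0
MIN_FOLLOWUP_MONTHS = 42.0

#: main-component control/intervention hazard ratios of the 7 scenarios;
#: the first entry reproduces the planning hazard 0.0100 exactly.
SCENARIO_HRS = (LAMBDA_MC_C / LAMBDA_MC_I, 1.3, 1.25, 1.2, 1.15, 1.1, 1.05)

#: per-group sample sizes of the reference designs (no futility stopping)
N_PER_GROUP = {
    Approach.IUT_SUP_SUP: 630,
    Approach.IUT_SUP_NI: 410,
    Approach.SINGLE_EP_TWO_FUT: 365,
}

#: published optimal futility pairs (composite, main component)
OPTIMAL_PAIRS = {
    Approach.IUT_SUP_SUP: (0.43, 0.44),
    Approach.IUT_SUP_NI: (0.65, 0.37),
    Approach.SINGLE_EP_TWO_FUT: (0.69, 0.65),
}


def planning_params(n_per_group: int) -> ScenarioParams:
    """Planning-assumption scenario (scenario 1)."""
    return ScenarioParams(
        lambda_mc_i=LAMBDA_MC_I,
        lambda_mc_c=LAMBDA_MC_C,
        lambda_other_i=LAMBDA_OTHER_I,
        lambda_other_c=LAMBDA_OTHER_C,
        recruit_months=RECRUIT_MONTHS,
        min_followup_months=MIN_FOLLOWUP_MONTHS,
        n_per_group=n_per_group,
    )


PLANNING_PARAMS = planning_params(N_PER_GROUP[Approach.IUT_SUP_SUP])


def scenario_params(hr_mc: float, n_per_group: int) -> ScenarioParams:
    """Deviation scenario: control main-component hazard = 0.0074 * hr_mc.

    The composite hazard stays at its planning value, so the control-arm
    non-fatal hazard compensates (``lambda_ce_c - lambda_mc_c``).
    """
    lam_mc_c = LAMBDA_MC_I * hr_mc
    lam_other_c = (LAMBDA_MC_C + LAMBDA_OTHER_C) - lam_mc_c
    if lam_other_c < 0:
        raise ValueError("main-component hazard exceeds the planning composite hazard")
    return replace(
        planning_params(n_per_group), lambda_mc_c=lam_mc_c, lambda_other_c=lam_other_c
    )


def design_spec(approach: Approach | str) -> DesignSpec:
    """Design configuration of the worked example for one approach."""
    approach = Approach(approach)
    return DesignSpec(
        approach=approach,
        alpha=0.025,
        target_power=0.90,
        info_fraction=0.5,
        level_method="pocock",
        ni_margin_hr=0.9 if approach is Approach.IUT_SUP_NI else 1.0,
        beta_l=0.05,
        gamma=0.025,
        theta_star_hr=1.2,
    )
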