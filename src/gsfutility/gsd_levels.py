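"""Local significance levels for two-stage group sequential designs, and a
closed-form single-endpoint operating-characteristics oracle.

The interim and final test statistics (Z1, Z2) are jointly normal with
correlation ``sqrt(t)`` where ``t`` is the information fraction at the
interim.  Local one-sided levels (alpha1, alpha2) are calibrated so that
the global one-sided type I error ``P(Z1 > z1 or Z2 > z2)`` equals alpha
under the null.  When a binding futility rule is added on top, the local
levels are deliberately *not* increased to re-exhaust alpha; the design is
then conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["LocalLevels", "local_levels", "analytic_single_endpoint_oc"]

_GLOBAL_LEVEL_TOL = 1e-8


def _bvn_cdf(x: float, y: float, rho: float) -> float:
    """P(Z1 <= x, Z2 <= y) for standard bivariate normal with corr rho."""
    if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
        return 0.0
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf(
            [min(x, 38.0), min(y, 38.0)]
        )
    )


@dataclass(frozen=True)
class LocalLevels:
    """One-sided local significance levels of a two-stage design."""

    alpha1: float
    alpha2: float
    stage_correlation: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < 1.0 and 0.0 < self.alpha2 < 1.0):
            raise ValueError("local levels must lie in (0, 1)")
        if not 0.0 < self.stage_correlation < 1.0:
            raise ValueError("stage correlation must lie in (0, 1)")

    @property
    def z1(self) -> float:
        return float(stats.norm.isf(self.alpha1))

    @property
    def z2(self) -> float:
        return float(stats.norm.isf(self.alpha2))

    def global_level(self) -> float:
        """P(Z1 > z1 or Z2 > z2) under the bivariate normal null."""
        return 1.0 - _bvn_cdf(self.z1, self.z2, self.stage_correlation)


def local_levels(alpha: float, info_fraction: float, method: str = "pocock") -> LocalLevels:
    """Local one-sided levels for a two-stage design.

    ``method='pocock'`` uses constant levels alpha1 = alpha2; ``'obf'``
    (O'Brien-Fleming) uses z-boundaries ``c / sqrt(t_k)`` with
    ``t_1 = info_fraction`` and ``t_2 = 1``, conservative early and liberal
    late.  In both cases the boundary constant solves the global level
    equation by bracketing root search to high accuracy.

    For ``alpha = 0.025`` and ``info_fraction = 0.5`` the Pocock local
    level is about 0.0147 (z about 2.178).
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if not 0.0 < info_fraction < 1.0:
        raise ValueError("info_fraction must lie in (0, 1)")
    rho = float(np.sqrt(info_fraction))

    if method == "pocock":
        def residual(z: float) -> float:
            return (1.0 - _bvn_cdf(z, z, rho)) - alpha

        z = optimize.brentq(residual, 0.5, 8.0, xtol=1e-12)
        a = float(stats.norm.sf(z))
        return LocalLevels(alpha1=a, alpha2=a, stage_correlation=rho, method="pocock")
    if method == "obf":
        def residual(c: float) -> float:
            return (1.0 - _bvn_cdf(c / rho, c, rho)) - alpha

        c = optimize.brentq(residual, 0.5, 8.0, xtol=1e-12)
        return LocalLevels(
            alpha1=float(stats.norm.sf(c / rho)),
            alpha2=float(stats.norm.sf(c)),
            stage_correlation=rho,
            method="obf",
        )
    raise ValueError("method must be 'pocock' or 'obf'")


def analytic_single_endpoint_oc(
    drift1: float,
    drift2: float,
    levels: LocalLevels,
    futility_bound: float,
) -> dict[str, float]:
    """Exact operating characteristics of a single-endpoint two-stage design.

    The statistics are ``Z1 ~ N(drift1, 1)`` and ``Z2 ~ N(drift2, 1)`` with
    correlation ``levels.stage_correlation``.  Stage 1 rejects when the
    one-sided p-value p1 <= alpha1 (Z1 >= z1), stops for futility when
    p1 >= futility_bound (Z1 <= zf, a binding rule), and continues
    otherwise; stage 2 rejects when p2 <= alpha2.

    Returns stage-1 efficacy / futility / continuation probabilities and
    the overall power; the three stage-1 probabilities sum to 1.
    """
    if not futility_bound > levels.alpha1:
        raise ValueError("futility_bound must exceed alpha1 (empty continuation region)")
    z1, z2 = levels.z1, levels.z2
    rho = levels.stage_correlation
    zf = -np.inf if futility_bound >= 1.0 else float(stats.norm.isf(futility_bound))

    p_eff = float(stats.norm.sf(z1 - drift1))
    p_fut = float(stats.norm.cdf(zf - drift1))
    p_cont = max(1.0 - p_eff - p_fut, 0.0)

    # P(zf < Z1 < z1, Z2 > z2), shifted to zero-mean coordinates
    def upper_strip(zcut: float) -> float:
        # P(Z1 < zcut, Z2 > z2) = P(Z1 < zcut) - P(Z1 < zcut, Z2 < z2)
        if np.isinf(zcut) and zcut < 0:
            return 0.0
        return float(stats.norm.cdf(zcut - drift1)) - _bvn_cdf(
            zcut - drift1, z2 - drift2, rho
        )

    p_cont_reject = max(upper_strip(z1) - upper_strip(zf), 0.0)
    return {
        "p_stop_efficacy_stage1": p_eff,
        "p_stop_futility_stage1": p_fut,
        "p_continue": p_cont,
        "overall_power": p_eff + p_cont_reject,
    }
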