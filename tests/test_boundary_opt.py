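"""Boundary search: agreement with an exhaustive per-pair oracle, upward
closure of admissibility, frontier extraction and optimal-pair selection."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gsfutility import (
    FutilityPair,
    admissible_set,
    futility_grid,
    operating_characteristics,
    optimal_pair,
)


def _search(matrix_h1, matrix_star, spec, levels, step=0.1, **overrides):
    spec = dataclasses.replace(spec, **overrides) if overrides else spec
    return spec, optimal_pair(admissible_set(matrix_h1, matrix_star, spec, levels, step))


def test_grid_excludes_levels_and_is_step_spaced(pocock_levels):
    g = futility_grid(pocock_levels, 0.01)
    assert g[0] > pocock_levels.alpha1
    assert g[-1] == 1.0
    assert np.allclose(np.diff(g), 0.01)
    with pytest.raises(ValueError):
        futility_grid(pocock_levels, 0.0)


def test_grid_evaluation_matches_per_pair_oracle(
    matrix_h1_small, matrix_star_small, spec_a1, pocock_levels
):
    """Common-random-number evaluation: the vectorised grid quantities equal
    a fresh per-pair pass through the decision rule, exactly."""
    fr = admissible_set(matrix_h1_small, matrix_star_small, spec_a1, pocock_levels, 0.1)
    for i, a1 in enumerate(fr.grid_ep1):
        for j, a2 in enumerate(fr.grid_ep2):
            oc1 = operating_characteristics(
                matrix_h1_small, spec_a1, pocock_levels, FutilityPair(a1, a2)
            )
            oc4 = operating_characteristics(
                matrix_star_small, spec_a1, pocock_levels, FutilityPair(a1, a2)
            )
            assert fr.wrongly_rate[i, j] == oc1.p_stop_futility_stage1
            assert fr.power_h1[i, j] == oc1.overall_power
            assert fr.correctly_rate[i, j] == oc4.p_stop_futility_stage1
            raw_ok = (
                oc1.overall_power >= spec_a1.target_power - spec_a1.beta_l - 1e-12
                and oc1.p_stop_futility_stage1 <= spec_a1.gamma + 1e-12
            )
            if raw_ok:
                assert fr.admissible[i, j]


def test_admissibility_is_upward_closed(
    matrix_h1_small, matrix_star_small, spec_a1, pocock_levels
):
    fr = admissible_set(matrix_h1_small, matrix_star_small, spec_a1, pocock_levels, 0.05)
    adm = fr.admissible
    assert np.array_equal(adm, np.logical_or.accumulate(adm, axis=0))
    assert np.array_equal(adm, np.logical_or.accumulate(adm, axis=1))
    # frontier members are admissible and not dominated
    ii, jj = np.nonzero(fr.frontier)
    for i, j in zip(ii, jj):
        assert adm[i, j]
        assert not (i > 0 and adm[i - 1, j])
        assert not (j > 0 and adm[i, j - 1])


def test_vacuous_constraints_make_everything_admissible(
    matrix_h1_small, matrix_star_small, spec_a1, pocock_levels
):
    spec, fr = _search(
        matrix_h1_small, matrix_star_small, spec_a1, pocock_levels,
        beta_l=1.0, gamma=1.0,
    )
    assert fr.admissible.all()
    # the only Pareto-minimal pair is the smallest one, and it is optimal
    # (the correctly-stopping rate is non-increasing in each bound)
    assert fr.frontier.sum() == 1
    assert fr.frontier[0, 0]
    assert fr.optimal == FutilityPair(float(fr.grid_ep1[0]), float(fr.grid_ep2[0]))
    assert fr.optimal_correct_rate == fr.correctly_rate.max()


def test_impossible_constraints_yield_no_admissible_boundary(
    matrix_h1_small, matrix_star_small, spec_a1, pocock_levels
):
    """beta_l = gamma = 0 demands the unconstrained power with zero futility
    stops; on a matrix whose reference power is below the target this is
    unattainable and the search reports 'no admissible boundary'."""
    spec, fr = _search(
        matrix_h1_small, matrix_star_small, spec_a1, pocock_levels,
        beta_l=0.0, gamma=0.0,
    )
    assert fr.n_admissible == 0
    assert fr.optimal is None
    assert np.isnan(fr.optimal_correct_rate)


def test_optimal_pair_matches_exhaustive_argmax(
    matrix_h1_small, matrix_star_small, spec_a1, pocock_levels
):
    # tolerances wide enough for a non-trivial admissible set at this small n
    # (the reference power at n=200 per group is ~0.35, far below target)
    spec, fr = _search(
        matrix_h1_small, matrix_star_small, spec_a1, pocock_levels, 0.1,
        beta_l=0.6, gamma=0.05,
    )
    assert fr.optimal is not None
    best = None
    for i, a1 in enumerate(fr.grid_ep1):
        for j, a2 in enumerate(fr.grid_ep2):
            if not fr.admissible[i, j]:
                continue
            key = (fr.correctly_rate[i, j], a1 + a2, a1)
            if best is None or key > best[0]:
                best = (key, (a1, a2))
    assert fr.optimal == FutilityPair(*best[1])
    assert fr.optimal_correct_rate == best[0][0]
    # the optimum satisfies both constraints with observed proportions
    i = int(np.searchsorted(fr.grid_ep1, fr.optimal.af_ep1))
    j = int(np.searchsorted(fr.grid_ep2, fr.optimal.af_ep2))
    assert fr.wrongly_rate[i, j] <= spec.gamma + 1e-12
    assert fr.power_h1[i, j] >= spec.target_power - spec.beta_l - 1e-12


def test_mismatched_matrices_refused(matrix_h1_small, spec_a1, pocock_levels):
    short = dataclasses.replace(
        matrix_h1_small,
        p1_ce=matrix_h1_small.p1_ce[:100], p1_mc=matrix_h1_small.p1_mc[:100],
        p2_ce=matrix_h1_small.p2_ce[:100], p2_mc=matrix_h1_small.p2_mc[:100],
        d1_ce=matrix_h1_small.d1_ce[:100], d2_ce=matrix_h1_small.d2_ce[:100],
    )
    with pytest.raises(ValueError):
        admissible_set(matrix_h1_small, short, spec_a1, pocock_levels, 0.1)
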