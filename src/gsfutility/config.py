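"""Experiment configuration and the two report-generating drivers.

A flat YAML (or JSON) file describes one experiment: scenario hazards,
trial schedule, design, simulation size, seed and grid settings.  The two
drivers write long-format CSV tables (one row per combination) plus a log
of seeds and Monte-Carlo standard errors; every row carries the seed and a
hash of the configuration so any number is regenerable from the config
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boundary_opt import admissible_set, optimal_pair
from .designs import Approach, DesignSpec, FutilityPair
from .gsd_levels import local_levels
from .oc_engine import OCResult, operating_characteristics, oc_table
from .trial_model import ScenarioParams, interim_calendar_time, simulate_pvalue_matrix

__all__ = ["ExperimentConfig", "run_oc_experiment", "run_boundary_search"]

log = logging.getLogger("gsfutility")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    ``scenario_hr_mc`` lists control/intervention hazard-ratio values for
    the main component (the control hazard is ``lambda_mc_i * hr``); the
    non-fatal hazards stay at their stated values in every scenario.
    ``theta_star_hr`` must appear in the list when a boundary search is
    run (it supplies the 'correctly' stopping scenario).
    """

    # trial schedule and planning hazards (per month / months)
    lambda_mc_i: float
    lambda_mc_c: float
    lambda_other_i: float
    lambda_other_c: float
    recruit_months: float
    min_followup_months: float
    n_per_group: int
    # design
    approach: str
    alpha: float = 0.025
    target_power: float = 0.90
    info_fraction: float = 0.5
    level_method: str = "pocock"
    ni_margin_hr: float = 1.0
    beta_l: float = 0.05
    gamma: float = 0.025
    theta_star_hr: float = 1.2
    # experiment
    scenario_hr_mc: tuple[float, ...] = ()
    futility_pairs: tuple[tuple[float, float], ...] = ()
    n_grid: tuple[int, ...] = ()
    n_sims: int = 10_000
    seed: int = 12345
    grid_step: float = 0.01
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.scenario_hr_mc:
            raise ValueError("scenario list must be non-empty")
        if any(hr <= 0 for hr in self.scenario_hr_mc):
            raise ValueError("scenario hazard-ratio multipliers must be positive")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        # validate nested objects eagerly, before any simulation starts
        self.design_spec()
        self.planning_params()

    # -- construction -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("scenario_hr_mc", "n_grid"):
            if key in d:
                d[key] = tuple(d[key])
        if "futility_pairs" in d:
            d["futility_pairs"] = tuple(tuple(p) for p in d["futility_pairs"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, **kw) -> "ExperimentConfig":
        kw = {k: v for k, v in kw.items() if v is not None}
        return replace(self, **kw)

    # -- derived objects ----------------------------------------------
    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            approach=Approach(self.approach),
            alpha=self.alpha,
            target_power=self.target_power,
            info_fraction=self.info_fraction,
            level_method=self.level_method,
            ni_margin_hr=self.ni_margin_hr,
            beta_l=self.beta_l,
            gamma=self.gamma,
            theta_star_hr=self.theta_star_hr,
        )

    def planning_params(self, n_per_group: int | None = None) -> ScenarioParams:
        return ScenarioParams(
            lambda_mc_i=self.lambda_mc_i,
            lambda_mc_c=self.lambda_mc_c,
            lambda_other_i=self.lambda_other_i,
            lambda_other_c=self.lambda_other_c,
            recruit_months=self.recruit_months,
            min_followup_months=self.min_followup_months,
            n_per_group=n_per_group or self.n_per_group,
        )

    def scenario_params(self, hr_mc: float, n_per_group: int | None = None) -> ScenarioParams:
        """Deviation confined to the main component: the composite hazard
        stays at its planning value and the control-arm non-fatal hazard
        compensates."""
        lam_mc_c = self.lambda_mc_i * hr_mc
        lam_other_c = (self.lambda_mc_c + self.lambda_other_c) - lam_mc_c
        if lam_other_c < 0:
            raise ValueError("scenario main-component hazard exceeds the composite hazard")
        return replace(
            self.planning_params(n_per_group),
            lambda_mc_c=lam_mc_c,
            lambda_other_c=lam_other_c,
        )

    def config_hash(self) -> str:
        """Hash of every field that affects the numbers (out_dir excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _scenario_seed(base_seed: int, scenario_idx: int, n: int) -> int:
    """Deterministic per-(scenario, n) child seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{scenario_idx}:{n}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_oc_experiment(config: ExperimentConfig, plot: bool = False) -> pd.DataFrame:
    """Operating characteristics per (scenario x futility pair x n).

    Writes ``oc_results.csv`` (long format) to the output directory and,
    when ``plot`` is set, curves of the futility-stop probability and the
    overall power against the per-group sample size.
    """
    spec = config.design_spec()
    levels = local_levels(spec.alpha, spec.info_fraction, spec.level_method)
    pairs = config.futility_pairs or ((0.5, 0.5),)
    n_grid = config.n_grid or (config.n_per_group,)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    t0 = time.time()
    results: list[OCResult] = []
    rows = []
    for n in n_grid:
        # interim cutoff fixed by the planning hazards, reused in deviations
        t_interim = interim_calendar_time(config.planning_params(n), config.info_fraction)
        for s_idx, hr in enumerate(config.scenario_hr_mc):
            seed = _scenario_seed(config.seed, s_idx, n)
            matrix = simulate_pvalue_matrix(
                config.scenario_params(hr, n),
                n_sims=config.n_sims,
                seed=seed,
                info_fraction=config.info_fraction,
                mc_margin_hr=spec.mc_margin_hr,
                interim_months=t_interim,
                scenario=f"hr_mc={hr:g}",
            )
            log.info("scenario hr=%g n=%d seed=%d interim=%.2f mo", hr, n, seed, t_interim)
            for af1, af2 in pairs:
                oc = operating_characteristics(matrix, spec, levels, FutilityPair(af1, af2))
                results.append(oc)
                row = oc.to_row()
                row.update(hr_mc=hr, n_per_group=n, config_hash=chash)
                rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(out / "oc_results.csv", index=False)
    log.info("oc experiment: %d rows in %.1f s -> %s", len(table), time.time() - t0,
             out / "oc_results.csv")
    if plot:
        _plot_oc_curves(table, out)
    return table


def _plot_oc_curves(table: pd.DataFrame, out: Path) -> None:
    """Futility-stop probability and overall power vs per-group n."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharex=True)
    for hr, grp in table.groupby("hr_mc"):
        grp = grp.sort_values("n_per_group")
        axes[0].plot(grp["n_per_group"], grp["p_stop_futility_stage1"], label=f"HR={hr:g}")
        axes[1].plot(grp["n_per_group"], grp["overall_power"], label=f"HR={hr:g}")
    axes[0].set_ylabel("P(stop for futility)")
    axes[1].set_ylabel("overall power")
    for ax in axes:
        ax.set_xlabel("n per group")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "oc_curves.png", dpi=150)
    plt.close(fig)


def run_boundary_search(config: ExperimentConfig) -> dict:
    """Admissibility frontier and optimal futility pair.

    Simulates the planning scenario and the theta* scenario with common
    random numbers, evaluates the full futility grid, and writes
    ``frontier.csv`` (one row per evaluated pair) and ``search_report.json``
    with the admissible count, the optimal pair and exhaustion diagnostics.
    """
    spec = config.design_spec()
    levels = local_levels(spec.alpha, spec.info_fraction, spec.level_method)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    params_h1 = config.planning_params()
    t_interim = interim_calendar_time(params_h1, config.info_fraction)
    common = dict(
        n_sims=config.n_sims,
        seed=config.seed,
        info_fraction=config.info_fraction,
        mc_margin_hr=spec.mc_margin_hr,
        interim_months=t_interim,
    )
    matrix_h1 = simulate_pvalue_matrix(params_h1, scenario="planning", **common)
    matrix_star = simulate_pvalue_matrix(
        config.scenario_params(spec.theta_star_hr), scenario="theta_star", **common
    )
    frontier = optimal_pair(
        admissible_set(matrix_h1, matrix_star, spec, levels, config.grid_step)
    )
    frontier.to_frame().assign(config_hash=config.config_hash(), seed=config.seed).to_csv(
        out / "frontier.csv", index=False
    )

    report: dict = {
        "approach": spec.approach.value,
        "n_per_group": config.n_per_group,
        "n_sims": config.n_sims,
        "seed": config.seed,
        "grid_step": config.grid_step,
        "interim_months": t_interim,
        "n_grid_pairs": int(frontier.admissible.size),
        "n_admissible": frontier.n_admissible,
        "n_frontier": int(frontier.frontier.sum()),
        "n_closure_fixes": frontier.n_closure_fixes,
        "config_hash": config.config_hash(),
        "runtime_s": round(time.time() - t0, 2),
    }
    if frontier.optimal is None:
        report["optimal"] = None
    else:
        g1 = np.searchsorted(frontier.grid_ep1, frontier.optimal.af_ep1)
        g2 = np.searchsorted(frontier.grid_ep2, frontier.optimal.af_ep2)
        report["optimal"] = {
            "af_ce": frontier.optimal.af_ep1,
            "af_mc": frontier.optimal.af_ep2,
            "correctly_stopping_rate": frontier.optimal_correct_rate,
            "wrongly_stopping_rate": float(frontier.wrongly_rate[g1, g2]),
            "power_loss": float(config.target_power - frontier.power_h1[g1, g2]),
            # exhaustion diagnostics: fraction of each tolerance actually used
            "gamma_exhaustion": float(frontier.wrongly_rate[g1, g2] / spec.gamma)
            if spec.gamma > 0 else np.nan,
            "beta_l_exhaustion": float(
                (config.target_power - frontier.power_h1[g1, g2]) / spec.beta_l
            ) if spec.beta_l > 0 else np.nan,
        }
    with open(out / "search_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("boundary search done in %.1f s -> %s", report["runtime_s"], out)
    return report
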