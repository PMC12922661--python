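"""The two simulation studies.

Parameter recovery: each participant's fitted parameters are treated as
ground truth; full agent-environment sessions are simulated from them
(3 per participant), refit with the identical priors, and recovery is
summarised as the Pearson correlation between true and recovered values of
each free parameter across participants.

Belief-behavior mapping: with every other fitted parameter held fixed, the
initial volatility prior μ₃⁰ is swept over a 15-point grid spanning the
15th-85th percentiles of its empirical distribution. At each grid value 100
sessions are simulated per participant and their win-switch rates averaged,
yielding a subject-level μ₃⁰→WSR curve. Curves are averaged over all
participants (the model-predicted belief-behavior mapping) and within
low/high metacognition groups (±1 SD of z-scored M̄); a linear regression on
the two group-mean curves with a group interaction tests whether the
belief→behavior slope is shallower at high metacognition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .behavior import win_switch_rate
from .hgf import FitFailureError, HGFParams, ParamPrior, fit_map, simulate_agent
from .inference import zscore
from .prl import TaskConfig

__all__ = [
    "RecoveryReport",
    "MappingResult",
    "parameter_recovery",
    "belief_behavior_mapping",
]


@dataclass
class RecoveryReport:
    """True vs recovered parameters, one row per participant x repetition."""

    table: pd.DataFrame  # participant, rep, converged, true_<p>, recovered_<p>
    correlations: dict[str, tuple[float, float]]  # param -> (r, one-sided p)
    undefined: tuple[str, ...]  # params with zero truth variance
    n_failed: int
    n_reps: int


@dataclass
class MappingResult:
    """μ₃⁰→WSR mapping curves and the group-interaction test."""

    grid: np.ndarray
    subject_curves: pd.DataFrame  # participants x grid points
    population_curve: np.ndarray
    low_curve: np.ndarray
    high_curve: np.ndarray
    n_low: int
    n_high: int
    slope_low: float
    slope_high: float
    slope_diff: float
    p_interaction: float
    n_reps: int


def parameter_recovery(
    true_params: dict[str, HGFParams],
    config: TaskConfig,
    priors: ParamPrior,
    n_reps: int = 3,
    seed: int | None = None,
    n_restarts: int = 3,
) -> RecoveryReport:
    """Simulate-and-refit recovery for every participant's parameters.

    Failed refits are recorded (``converged`` False) and excluded from the
    correlations; the report counts them. Correlation is undefined (flagged)
    for a parameter whose true values have zero variance.
    """
    if len(true_params) < 2:
        raise ValueError("need at least 2 participants")
    free = priors.free_names
    root = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for pid in sorted(true_params):
        truth = true_params[pid]
        for rep in range(n_reps):
            sim_seed = root.integers(2**31)
            fit_seed = root.integers(2**31)
            session, _ = simulate_agent(truth, config, int(sim_seed), participant_id=pid)
            row: dict = {"participant": pid, "rep": rep}
            for name in free:
                row[f"true_{name}"] = getattr(truth, name)
            try:
                fit = fit_map(session, priors, n_restarts=n_restarts, seed=int(fit_seed))
                row["converged"] = True
                for name in free:
                    row[f"recovered_{name}"] = getattr(fit.params, name)
            except FitFailureError:
                n_failed += 1
                row["converged"] = False
                for name in free:
                    row[f"recovered_{name}"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)

    correlations: dict[str, tuple[float, float]] = {}
    undefined = []
    ok = table[table["converged"]]
    for name in free:
        truth_vals = ok[f"true_{name}"].to_numpy()
        rec_vals = ok[f"recovered_{name}"].to_numpy()
        if len(truth_vals) < 3 or np.std(truth_vals) == 0:
            undefined.append(name)
            continue
        r, p_two = sps.pearsonr(truth_vals, rec_vals)
        p_one = p_two / 2.0 if r > 0 else 1.0 - p_two / 2.0
        correlations[name] = (float(r), float(p_one))
    return RecoveryReport(
        table=table,
        correlations=correlations,
        undefined=tuple(undefined),
        n_failed=n_failed,
        n_reps=n_reps,
    )


def _expected_wsr(
    params: HGFParams, config: TaskConfig, n_reps: int, rng: np.random.Generator
) -> float:
    """Mean WSR over repeated simulated sessions (sessions with no rewarded
    trial before the last carry no WSR and are skipped)."""
    vals = []
    for _ in range(n_reps):
        session, _ = simulate_agent(params, config, rng, record=False)
        summary = win_switch_rate(session)
        if summary.wsr is not None:
            vals.append(summary.wsr)
    return float(np.mean(vals)) if vals else np.nan


def belief_behavior_mapping(
    fitted_params: dict[str, HGFParams],
    mp_scores: dict[str, float],
    config: TaskConfig,
    n_grid: int = 15,
    pct_lo: float = 15.0,
    pct_hi: float = 85.0,
    n_reps: int = 100,
    seed: int | None = None,
    tie_m3: bool = True,
    split_sd: float = 1.0,
) -> MappingResult:
    """Sweep μ₃⁰ over its empirical 15th-85th percentile range and map the
    induced change in expected win-switch rate.

    Only μ₃⁰ varies (with the level-3 attractor following it when
    ``tie_m3``); every other fitted parameter stays at its per-participant
    value, so any WSR change is attributable to the volatility prior alone.
    """
    pids = sorted(fitted_params)
    if set(pids) != set(mp_scores):
        raise ValueError("fitted_params and mp_scores must cover the same participants")
    mu3_values = np.array([fitted_params[p].mu3_0 for p in pids])
    lo, hi = np.percentile(mu3_values, [pct_lo, pct_hi])
    grid = np.linspace(lo, hi, n_grid)

    root = np.random.default_rng(seed)
    curves = np.empty((len(pids), n_grid))
    for i, pid in enumerate(pids):
        base = fitted_params[pid]
        rng = np.random.default_rng(root.integers(2**31))
        for g, mu3 in enumerate(grid):
            params = replace(base, mu3_0=float(mu3), m3=float(mu3) if tie_m3 else base.m3)
            curves[i, g] = _expected_wsr(params, config, n_reps, rng)
    subject_curves = pd.DataFrame(curves, index=pids, columns=grid)
    population_curve = np.nanmean(curves, axis=0)

    z_mp = zscore([mp_scores[p] for p in pids])
    low_mask = z_mp <= -split_sd
    high_mask = z_mp >= split_sd
    if not low_mask.any() or not high_mask.any():
        raise ValueError(
            "empty low/high metacognition group after the ±1 SD split; "
            "relax split_sd or use more participants"
        )
    low_curve = np.nanmean(curves[low_mask], axis=0)
    high_curve = np.nanmean(curves[high_mask], axis=0)

    # interaction regression on the two group-mean curves (15 points each)
    y = np.concatenate([low_curve, high_curve])
    x = np.concatenate([grid, grid])
    g = np.concatenate([np.zeros(n_grid), np.ones(n_grid)])
    X = sm.add_constant(np.column_stack([x, g, x * g]))
    ols = sm.OLS(y, X).fit()
    slope_low = float(ols.params[1])
    slope_diff = float(ols.params[3])
    return MappingResult(
        grid=grid,
        subject_curves=subject_curves,
        population_curve=population_curve,
        low_curve=low_curve,
        high_curve=high_curve,
        n_low=int(low_mask.sum()),
        n_high=int(high_mask.sum()),
        slope_low=slope_low,
        slope_high=slope_low + slope_diff,
        slope_diff=slope_diff,
        p_interaction=float(ols.pvalues[3]),
        n_reps=n_reps,
    )
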