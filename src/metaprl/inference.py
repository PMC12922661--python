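"""Group comparisons and the moderation analysis.

The central model is a binomial GLM (logit link) predicting each
participant's win-switch behavior from their volatility prior, metacognitive
structure, their interaction, and verbosity/cognition controls:

    WSR ~ β0 + β1 z(μ₃⁰) + β2 z(M̄) + β3 z(μ₃⁰)·z(M̄) + β4 z(V) + β5 z(C)

WSR enters as (win-switch count, win-trial count) binomial counts, which
weights participants by how many rewarded trials they actually had. All
regressors are z-scored. Interaction strength is tested by likelihood-ratio
test; effects are reported as odds ratios and average marginal effects; the
probability-scale story — how much a −1→+1 SD rise in the volatility prior
raises predicted switching at low versus high metacognition — is quantified
with participant-resampling bootstrap contrasts in percentage points.
Because predicted probabilities bend near 0 and 1, those contrasts can
differ across metacognition levels even without a link-scale interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "REQUIRED_COLUMNS",
    "MIN_PARTICIPANTS",
    "GLMFit",
    "ContrastResult",
    "BPResult",
    "GroupCompareResult",
    "zscore",
    "build_moderation_table",
    "fit_moderation",
    "lrt",
    "odds_ratio",
    "average_marginal_effect",
    "predicted_wsr",
    "bootstrap_contrast",
    "breusch_pagan",
    "group_compare",
]

REQUIRED_COLUMNS = ("n_win_switches", "n_win_trials", "mu3_0", "m_bar", "verbosity", "gcog")
MIN_PARTICIPANTS = 10

_TERMS_FULL = ("const", "z_mu3", "z_mp", "z_mu3:z_mp", "z_verbosity", "z_gcog")


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardise to mean 0 and sample SD 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class GLMFit:
    """A fitted binomial GLM plus the design it was fitted on."""

    result: sm.GLM  # statsmodels GLMResults
    terms: tuple[str, ...]
    exog: np.ndarray
    endog: np.ndarray
    n_excluded: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.terms)

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    def cov_params(self) -> np.ndarray:
        return np.asarray(self.result.cov_params())


@dataclass(frozen=True)
class ContrastResult:
    """Bootstrap probability-scale contrast of the volatility-prior effect at
    low vs high metacognition, in percentage points."""

    pp_low: float
    pp_high: float
    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n_failed: int = 0


@dataclass(frozen=True)
class BPResult:
    lm_stat: float
    lm_df: int
    lm_p: float
    f_stat: float
    f_p: float


@dataclass(frozen=True)
class GroupCompareResult:
    stat: float
    p: float
    kind: str  # "welch_t" | "welch_anova"
    cohen_d: float | None = None
    df: float | None = None


def build_moderation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and subset a participant table for the moderation model.

    Participants with zero win trials carry no information about switching
    after reward; they are excluded (the count is reported by the fit).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"moderation table missing columns: {missing}")
    bad = df["n_win_switches"] > df["n_win_trials"]
    if bad.any():
        raise ValueError("n_win_switches may not exceed n_win_trials")
    return df.copy()


def _design(
    df: pd.DataFrame, include_interaction: bool, include_controls: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    z_mu3 = zscore(df["mu3_0"])
    z_mp = zscore(df["m_bar"])
    cols = [np.ones(len(df)), z_mu3, z_mp]
    terms = ["const", "z_mu3", "z_mp"]
    if include_interaction:
        cols.append(z_mu3 * z_mp)
        terms.append("z_mu3:z_mp")
    if include_controls:
        cols.append(zscore(df["verbosity"]))
        cols.append(zscore(df["gcog"]))
        terms.extend(["z_verbosity", "z_gcog"])
    return np.column_stack(cols), tuple(terms)


def fit_moderation(
    table: pd.DataFrame,
    include_interaction: bool = True,
    include_controls: bool = True,
) -> GLMFit:
    """Fit the binomial moderation GLM on (switch count, win count) data."""
    df = build_moderation_table(table)
    usable = df[df["n_win_trials"] > 0]
    n_excluded = len(df) - len(usable)
    if len(usable) < MIN_PARTICIPANTS:
        raise ValueError(
            f"need at least {MIN_PARTICIPANTS} participants with win trials "
            f"(have {len(usable)})"
        )
    exog, terms = _design(usable, include_interaction, include_controls)
    endog = np.column_stack(
        [
            usable["n_win_switches"].to_numpy(float),
            (usable["n_win_trials"] - usable["n_win_switches"]).to_numpy(float),
        ]
    )
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    result = model.fit()
    if not result.converged:
        raise RuntimeError("IRLS did not converge (possible separation)")
    return GLMFit(result=result, terms=terms, exog=exog, endog=endog, n_excluded=n_excluded)


def lrt(full: GLMFit, reduced: GLMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested binomial GLMs: 2·(llf_full − llf_red),
    df = parameter-count difference."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms must be a strict subset of the full model's")
    stat = 2.0 * (full.llf - reduced.llf)
    stat = max(stat, 0.0)
    df = len(full.terms) - len(reduced.terms)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return float(stat), df, p


def odds_ratio(fit: GLMFit, term: str) -> tuple[float, tuple[float, float]]:
    """exp(coefficient) with Wald 95% CI on the OR scale."""
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in model {fit.terms}")
    i = fit.terms.index(term)
    beta = float(fit.result.params[i])
    se = float(np.sqrt(fit.cov_params()[i, i]))
    zcrit = sps.norm.ppf(0.975)
    return float(np.exp(beta)), (float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se)))


def average_marginal_effect(fit: GLMFit, term: str) -> float:
    """Mean over observations of ∂p/∂x = β·p(1−p) on the probability scale."""
    if term not in fit.terms:
        raise ValueError(f"term {term!r} not in model {fit.terms}")
    i = fit.terms.index(term)
    beta = float(fit.result.params[i])
    p = fit.result.predict(fit.exog)
    return float(np.mean(beta * p * (1.0 - p)))


def predicted_wsr(fit: GLMFit, mu3_z: float, mp_z: float) -> float:
    """Model-predicted switch probability at a (z(μ₃⁰), z(M̄)) grid point with
    control covariates held at 0 (their z-scored mean)."""
    eta = 0.0
    values = {
        "const": 1.0,
        "z_mu3": mu3_z,
        "z_mp": mp_z,
        "z_mu3:z_mp": mu3_z * mp_z,
        "z_verbosity": 0.0,
        "z_gcog": 0.0,
    }
    for term, beta in zip(fit.terms, fit.result.params):
        eta += float(beta) * values[term]
    return float(1.0 / (1.0 + np.exp(-eta)))


def _contrast_pair(fit: GLMFit) -> tuple[float, float]:
    """(pp_low, pp_high): percentage-point change in predicted switching for
    μ₃⁰ going −1→+1 SD, at M̄ = −1 SD and +1 SD."""
    pp_low = 100.0 * (predicted_wsr(fit, +1.0, -1.0) - predicted_wsr(fit, -1.0, -1.0))
    pp_high = 100.0 * (predicted_wsr(fit, +1.0, +1.0) - predicted_wsr(fit, -1.0, +1.0))
    return pp_low, pp_high


def bootstrap_contrast(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    include_controls: bool = True,
    max_fail_frac: float = 0.05,
) -> ContrastResult:
    """Nonparametric bootstrap of the probability-scale contrast.

    Participants (rows) are resampled with replacement; the full GLM with
    interaction is refit each iterate and the pp contrasts recomputed; the
    95% CI for Δ = pp_high − pp_low is percentile-based. The z-scored design
    stays anchored to the observed table so the ±1 SD grid means the same
    thing in every iterate. Reproducible given ``seed``.
    """
    df = build_moderation_table(table)
    df = df[df["n_win_trials"] > 0].reset_index(drop=True)
    point_fit = fit_moderation(df, include_interaction=True, include_controls=include_controls)
    pp_low, pp_high = _contrast_pair(point_fit)

    # freeze standardised columns from the observed table
    frozen = df.copy()
    frozen["mu3_0"] = zscore(df["mu3_0"])
    frozen["m_bar"] = zscore(df["m_bar"])
    frozen["verbosity"] = zscore(df["verbosity"])
    frozen["gcog"] = zscore(df["gcog"])

    rng = np.random.default_rng(seed)
    n = len(frozen)
    deltas = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = frozen.iloc[idx]
        exog, terms = _design_frozen(boot, include_controls)
        endog = np.column_stack(
            [
                boot["n_win_switches"].to_numpy(float),
                (boot["n_win_trials"] - boot["n_win_switches"]).to_numpy(float),
            ]
        )
        try:
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            if not res.converged or not np.all(np.isfinite(res.params)):
                raise RuntimeError
        except Exception:
            n_failed += 1
            continue
        bfit = GLMFit(result=res, terms=terms, exog=exog, endog=endog)
        lo, hi = _contrast_pair(bfit)
        deltas.append(hi - lo)
    if n_failed > max_fail_frac * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed")
    ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    return ContrastResult(
        pp_low=pp_low,
        pp_high=pp_high,
        delta=pp_high - pp_low,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        n_failed=n_failed,
    )


def _design_frozen(df: pd.DataFrame, include_controls: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix from already-standardised columns (bootstrap path)."""
    cols = [np.ones(len(df)), df["mu3_0"].to_numpy(), df["m_bar"].to_numpy()]
    terms = ["const", "z_mu3", "z_mp"]
    cols.append(df["mu3_0"].to_numpy() * df["m_bar"].to_numpy())
    terms.append("z_mu3:z_mp")
    if include_controls:
        cols.append(df["verbosity"].to_numpy())
        cols.append(df["gcog"].to_numpy())
        terms.extend(["z_verbosity", "z_gcog"])
    return np.column_stack(cols), tuple(terms)


def breusch_pagan(response: Sequence[float], predictors: np.ndarray) -> BPResult:
    """Breusch–Pagan heteroscedasticity test: regress squared OLS residuals
    on the predictors; LM = n·R²; df = number of predictors. The companion
    F form is reported alongside. This is the diagnostic that motivates a
    binomial GLM over OLS for a bounded, mean-variance-coupled outcome."""
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    exog = sm.add_constant(X)
    ols = sm.OLS(y, exog).fit()
    if np.allclose(ols.resid, 0.0, atol=1e-12):
        # a perfect fit has nothing to be heteroscedastic about
        return BPResult(lm_stat=0.0, lm_df=X.shape[1], lm_p=1.0, f_stat=0.0, f_p=1.0)
    lm_stat, lm_p, f_stat, f_p = het_breuschpagan(ols.resid, exog)
    return BPResult(
        lm_stat=float(lm_stat),
        lm_df=X.shape[1],
        lm_p=float(lm_p),
        f_stat=float(f_stat),
        f_p=float(f_p),
    )


def group_compare(values: Sequence[float], groups: Sequence) -> GroupCompareResult:
    """Welch two-sample t (with pooled-SD Cohen's d) for two groups; Welch
    one-way ANOVA for more than two levels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == lev] for lev in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    if len(levels) == 2:
        a, b = samples
        t, p = sps.ttest_ind(a, b, equal_var=False)
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        return GroupCompareResult(stat=float(t), p=float(p), kind="welch_t", cohen_d=d)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    df = pd.DataFrame({"value": values, "group": groups})
    aov = pg.welch_anova(data=df, dv="value", between="group")
    return GroupCompareResult(
        stat=float(aov["F"].iloc[0]),
        p=float(aov["p_unc"].iloc[0]),
        kind="welch_anova",
        df=float(aov["ddof2"].iloc[0]),
    )
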