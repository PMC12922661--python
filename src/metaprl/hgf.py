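"""Three-level mean-reverting Hierarchical Gaussian Filter for a 3-armed
binary bandit, with a volatility-dependent softmax response model.

Levels, top down: level 3 tracks log-volatility of the environment, level 2
tracks the log-odds of reward for each option, level 1 is the binary
feedback itself. Both latent levels carry AR(1) (mean-reverting) dynamics:
between trials the state drifts toward an attractor ``m`` at rate ``phi``.

Per trial, with chosen option c and outcome y:

    prediction:  x̂2_j = μ2_j + φ2 (m2 − μ2_j)          (every option j)
                 x̂3   = μ3  + φ3 (m3 − μ3)
                 σ̂2_j = σ2_j + exp(κ x̂3 + ω)
                 σ̂3   = σ3 + θ
                 m̂_j  = s(x̂2_j)                         (logistic sigmoid)
    level 2:     δ1 = y − m̂_c
                 π2 = 1/σ̂2_c + m̂_c (1 − m̂_c)
                 μ2_c = x̂2_c + δ1 / π2 ;  σ2_c = 1/π2
                 unchosen options only drift and diffuse
    level 3:     w2 = exp(κ x̂3 + ω) / σ̂2_c
                 δ2 = (σ2_c + (μ2_c − x̂2_c)²) / σ̂2_c − 1
                 π3 = 1/σ̂3 + ½ κ² w2 (w2 + (2 w2 − 1) δ2)
                 μ3 = x̂3 + ½ κ w2 δ2 / π3 ;  σ3 = 1/π3

The response model maps predicted outcome probabilities to choice
probabilities through a softmax whose inverse temperature is tied to the
current volatility prediction, β(t) = exp(−x̂3(t)): an agent that expects a
changeable world chooses more noisily. β uses the *pre-outcome* prediction,
so a choice never conditions on the outcome it produces.

MAP fitting maximises choice log-likelihood plus Gaussian log-priors over
the free parameters in an unbounded estimation space (log for variance-like
parameters, logit for rates). Parameters with zero prior variance are fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .prl import SessionData, TaskConfig, TrialRecord, run_session

__all__ = [
    "HGFParams",
    "ParamPrior",
    "BeliefTrajectory",
    "FitResult",
    "InstabilityError",
    "FitFailureError",
    "HGFAgent",
    "filter_beliefs",
    "response_probabilities",
    "simulate_agent",
    "fit_map",
    "load_priors",
    "default_priors",
]

_PENALTY = 1e12


class InstabilityError(RuntimeError):
    """Non-positive posterior precision during filtering."""

    def __init__(self, trial: int, message: str | None = None) -> None:
        self.trial = trial
        super().__init__(message or f"belief update unstable at trial {trial}")


class FitFailureError(RuntimeError):
    """All optimisation restarts were unstable or non-finite."""


@dataclass(frozen=True)
class HGFParams:
    """Perceptual + response parameters.

    mu3_0 is the initial volatility prior: the anticipatory belief, before
    any feedback, about how changeable the contingencies are. kappa couples
    level-3 volatility into level-2 learning; omega is the tonic level-2
    log-volatility; theta the level-3 innovation variance. phi/m pairs give
    the AR(1) reversion rate and attractor of each latent level.
    """

    mu3_0: float = -2.6
    sigma3_0: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    kappa: float = 0.2
    omega: float = -0.5
    theta: float = 0.1
    phi2: float = 0.05
    m2: float = 0.0
    phi3: float = 0.05
    m3: float = -2.6

    def __post_init__(self) -> None:
        if self.sigma3_0 <= 0 or self.sigma2_0 <= 0:
            raise ValueError("initial variances must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not (0.0 <= self.phi2 <= 1.0 and 0.0 <= self.phi3 <= 1.0):
            raise ValueError("phi rates must lie in [0, 1]")


@dataclass
class BeliefTrajectory:
    """Per-trial belief states (arrays indexed [trial] or [trial, option])."""

    xhat2: np.ndarray
    xhat3: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    sigma2: np.ndarray
    sigma3: np.ndarray
    mhat: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.xhat3)


@dataclass
class FitResult:
    params: HGFParams
    neg_log_joint: float
    converged: bool
    n_restarts_used: int
    free_names: tuple[str, ...] = ()


# --- estimation-space transforms -------------------------------------------

def _sigmoid(x: float) -> float:
    """Overflow-safe logistic sigmoid (saturates smoothly for |x| > 40)."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-min(x, 40.0)))
    ex = math.exp(max(x, -40.0))
    return ex / (1.0 + ex)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


#: parameter -> (to estimation space, to natural space)
_TRANSFORMS = {
    "mu3_0": (lambda v: v, lambda v: v),
    "sigma3_0": (math.log, math.exp),
    "mu2_0": (lambda v: v, lambda v: v),
    "sigma2_0": (math.log, math.exp),
    "kappa": (math.log, math.exp),
    "omega": (lambda v: v, lambda v: v),
    "theta": (math.log, math.exp),
    "phi2": (_logit, _inv_logit),
    "m2": (lambda v: v, lambda v: v),
    "phi3": (_logit, _inv_logit),
    "m3": (lambda v: v, lambda v: v),
}

_PARAM_ORDER = tuple(_TRANSFORMS)


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian priors over parameters in estimation space.

    ``means``/``variances`` map parameter name to prior mean and variance in
    the estimation space (log for variances/kappa/theta, logit for phi).
    Zero prior variance marks a parameter as fixed during inversion. With
    ``tie_m3`` the level-3 attractor m3 tracks mu3_0 instead of having its
    own entry honoured.
    """

    means: dict[str, float]
    variances: dict[str, float]
    tie_m3: bool = True

    def __post_init__(self) -> None:
        for name in _PARAM_ORDER:
            if name not in self.means or name not in self.variances:
                raise ValueError(f"prior missing parameter {name!r}")
            if self.variances[name] < 0:
                raise ValueError(f"prior variance for {name!r} must be >= 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in _PARAM_ORDER if self.variances[n] > 0)

    def mean_params(self) -> HGFParams:
        """Natural-space parameters at the prior means."""
        natural = {n: _TRANSFORMS[n][1](self.means[n]) for n in _PARAM_ORDER}
        if self.tie_m3:
            natural["m3"] = natural["mu3_0"]
        return HGFParams(**natural)

    def params_from_vector(self, values: Sequence[float]) -> HGFParams:
        """Natural-space parameters with free entries replaced by ``values``
        (estimation space)."""
        est = dict(self.means)
        for name, v in zip(self.free_names, values, strict=True):
            est[name] = float(v)
        natural = {n: _TRANSFORMS[n][1](est[n]) for n in _PARAM_ORDER}
        if self.tie_m3:
            natural["m3"] = natural["mu3_0"]
        return HGFParams(**natural)


def load_priors(path) -> ParamPrior:
    """Read a prior block (parameter -> {mean, variance}, plus options) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _priors_from_dict(raw)


def _priors_from_dict(raw: dict) -> ParamPrior:
    params = raw["parameters"]
    means = {k: float(v["mean"]) for k, v in params.items()}
    variances = {k: float(v["variance"]) for k, v in params.items()}
    tie_m3 = bool(raw.get("options", {}).get("tie_m3", True))
    return ParamPrior(means=means, variances=variances, tie_m3=tie_m3)


def default_priors() -> ParamPrior:
    """The packaged default prior configuration (only mu3_0 free)."""
    text = resources.files("metaprl.data").joinpath("default_priors.yaml").read_text()
    return _priors_from_dict(yaml.safe_load(text))


# --- filtering and response model -------------------------------------------

class HGFAgent:
    """Stateful HGF belief filter usable both as an environment agent and as
    an offline filter over recorded sessions."""

    def __init__(self, params: HGFParams, n_options: int = 3, record: bool = True) -> None:
        self.p = params
        self.n_options = n_options
        self.record = record
        self.mu2 = [params.mu2_0] * n_options
        self.sigma2 = [params.sigma2_0] * n_options
        self.mu3 = params.mu3_0
        self.sigma3 = params.sigma3_0
        self.t = 0
        self._pred: tuple | None = None
        self._rows: list[tuple] = []

    # prediction step (cached until the matching update)
    def predict(self) -> tuple[list[float], float, list[float], list[float], float]:
        if self._pred is None:
            p = self.p
            xh3 = self.mu3 + p.phi3 * (p.m3 - self.mu3)
            # cap the phasic-volatility exponent: beyond this the filter is in
            # a degenerate runaway regime and exp() would overflow
            diffusion = math.exp(min(p.kappa * xh3 + p.omega, 30.0))
            xh2 = [m + p.phi2 * (p.m2 - m) for m in self.mu2]
            sh2 = [s + diffusion for s in self.sigma2]
            mh = [_sigmoid(x) for x in xh2]
            sh3 = self.sigma3 + p.theta
            self._pred = (xh2, xh3, sh2, mh, sh3)
        return self._pred

    def choice_probabilities(self) -> list[float]:
        xh2, xh3, _, mh, _ = self.predict()
        return response_probabilities(mh, xh3)

    def choice_log_probability(self, choice: int) -> float:
        xh2, xh3, _, mh, _ = self.predict()
        beta = math.exp(-xh3)
        z = [beta * m for m in mh]
        zmax = max(z)
        lse = zmax + math.log(sum(math.exp(v - zmax) for v in z))
        return z[choice - 1] - lse

    def update(self, choice: int, outcome: int) -> None:
        p = self.p
        xh2, xh3, sh2, mh, sh3 = self.predict()
        self._pred = None
        self.t += 1
        c = choice - 1

        delta1 = outcome - mh[c]
        pih2 = 1.0 / sh2[c]
        pi2 = pih2 + mh[c] * (1.0 - mh[c])
        if pi2 <= 0 or sh2[c] <= 0:
            raise InstabilityError(self.t)
        mu2_c = xh2[c] + delta1 / pi2
        sigma2_c = 1.0 / pi2

        new_mu2 = list(xh2)
        new_sigma2 = list(sh2)
        new_mu2[c] = mu2_c
        new_sigma2[c] = sigma2_c
        self.mu2 = new_mu2
        self.sigma2 = new_sigma2

        w2 = math.exp(min(p.kappa * xh3 + p.omega, 30.0)) * pih2
        delta2 = (sigma2_c + (mu2_c - xh2[c]) ** 2) / sh2[c] - 1.0
        pih3 = 1.0 / sh3
        pi3 = pih3 + 0.5 * p.kappa**2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0 or sh3 <= 0:
            raise InstabilityError(self.t)
        self.mu3 = xh3 + 0.5 * p.kappa * w2 * delta2 / pi3
        self.sigma3 = 1.0 / pi3

        if self.record:
            self._rows.append(
                (xh2, xh3, list(self.mu2), self.mu3, list(self.sigma2), self.sigma3, mh, delta1, delta2)
            )

    # Agent protocol ---------------------------------------------------
    def act(self, t: int) -> Sequence[float]:
        return self.choice_probabilities()

    def learn(self, record: TrialRecord, next_probs: dict[int, float]) -> None:
        self.update(record.choice, record.outcome)

    def trajectory(self) -> BeliefTrajectory:
        if not self._rows:
            raise ValueError("no recorded trials (record=False or nothing filtered)")
        cols = list(zip(*self._rows))
        return BeliefTrajectory(
            xhat2=np.array(cols[0]),
            xhat3=np.array(cols[1]),
            mu2=np.array(cols[2]),
            mu3=np.array(cols[3]),
            sigma2=np.array(cols[4]),
            sigma3=np.array(cols[5]),
            mhat=np.array(cols[6]),
            delta1=np.array(cols[7]),
            delta2=np.array(cols[8]),
        )


def response_probabilities(mhat: Sequence[float], xhat3: float) -> list[float]:
    """Volatility-dependent softmax over predicted reward probabilities.

    β = exp(−x̂3): higher inferred volatility means noisier choice. Computed
    via a max-shifted softmax, so extreme β never overflows; outputs are a
    strictly positive simplex point.
    """
    beta = math.exp(-xhat3)
    z = [beta * float(m) for m in mhat]
    zmax = max(z)
    ez = [math.exp(v - zmax) for v in z]
    total = sum(ez)
    probs = [max(v / total, 1e-300) for v in ez]
    s = sum(probs)
    return [v / s for v in probs]


def filter_beliefs(
    session: SessionData, params: HGFParams, n_options: int = 3
) -> BeliefTrajectory:
    """Run the forward filter over a recorded session.

    Deterministic given inputs; raises :class:`InstabilityError` (carrying
    the trial index) if any posterior precision turns non-positive.
    """
    agent = HGFAgent(params, n_options=n_options, record=True)
    for rec in session.records:
        agent.update(rec.choice, rec.outcome)
    return agent.trajectory()


def simulate_agent(
    params: HGFParams,
    config: TaskConfig,
    seed: int | np.random.Generator,
    participant_id: str = "sim",
    record: bool = True,
) -> tuple[SessionData, BeliefTrajectory | None]:
    """Closed-loop simulation: choices sampled from the volatility-dependent
    softmax, outcomes from the task schedule, beliefs updated each trial.
    ``record=False`` skips trajectory bookkeeping (returns None) for bulk
    simulation."""
    agent = HGFAgent(params, n_options=config.n_options, record=record)
    session = run_session(agent, config, seed, participant_id=participant_id)
    return session, agent.trajectory() if record else None


# --- MAP fitting ------------------------------------------------------------

def _neg_log_joint(
    x: np.ndarray,
    choices: Sequence[int],
    outcomes: Sequence[int],
    priors: ParamPrior,
    n_options: int,
) -> float:
    try:
        params = priors.params_from_vector(x)
    except (ValueError, OverflowError):
        return _PENALTY
    agent = HGFAgent(params, n_options=n_options, record=False)
    ll = 0.0
    try:
        for c, y in zip(choices, outcomes):
            ll += agent.choice_log_probability(c)
            agent.update(c, y)
    except (InstabilityError, OverflowError):
        return _PENALTY
    for name, v in zip(priors.free_names, x):
        var = priors.variances[name]
        ll -= 0.5 * (v - priors.means[name]) ** 2 / var + 0.5 * math.log(2 * math.pi * var)
    if not math.isfinite(ll):
        return _PENALTY
    return -ll


def fit_map(
    session: SessionData,
    priors: ParamPrior,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = None,
    n_options: int = 3,
) -> FitResult:
    """MAP inversion: maximise choice log-likelihood plus log-priors over the
    free parameters in estimation space, best of ``n_restarts`` jittered
    starts (first start at the prior mean). Fixed parameters (zero prior
    variance) are never touched. With no free parameters the prior means and
    their log-joint are returned directly.
    """
    if session.n_trials < 2:
        raise ValueError("need at least 2 trials to fit")
    choices = [int(c) for c in session.choices]
    outcomes = [int(y) for y in session.outcomes]
    free = priors.free_names

    if not free:
        nlj = _neg_log_joint(np.empty(0), choices, outcomes, priors, n_options)
        if nlj >= _PENALTY:
            raise FitFailureError("evaluation at prior means is unstable")
        return FitResult(priors.mean_params(), nlj, True, 0, free)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_vec = np.array([priors.means[n] for n in free])
    sd_vec = np.array([math.sqrt(priors.variances[n]) for n in free])

    best_x, best_nlj, best_ok = None, math.inf, False
    used = 0
    for r in range(n_restarts):
        x0 = mean_vec if r == 0 else mean_vec + rng.standard_normal(len(free)) * sd_vec
        used += 1
        res = minimize(
            _neg_log_joint,
            x0,
            args=(choices, outcomes, priors, n_options),
            method="BFGS",
            options={"maxiter": 200},
        )
        if res.fun < best_nlj and res.fun < _PENALTY:
            best_x, best_nlj, best_ok = res.x, float(res.fun), bool(res.success)
    if best_x is None:
        raise FitFailureError("all restarts unstable or non-finite")
    return FitResult(priors.params_from_vector(best_x), best_nlj, best_ok, used, free)
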