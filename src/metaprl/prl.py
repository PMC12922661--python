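"""Three-option probabilistic reversal learning (PRL) environment.

The task is a three-armed bandit with binary (win/loss) feedback. Reward
probabilities start at 90-50-10 and shift to 80-40-20 halfway through
(trial 81 of 160). The option-to-probability assignment reverses both on a
fixed schedule (every 40 trials) and whenever the participant exploits the
best option strongly enough (9 of the last 10 choices). Agents interact with
the environment through a small two-method protocol, so both hand-written
test agents and the Hierarchical Gaussian Filter agent plug in identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "AgentContractError",
    "TaskConfig",
    "TrialRecord",
    "SessionData",
    "Schedule",
    "Agent",
    "UniformAgent",
    "FixedAgent",
    "GreedyOracleAgent",
    "build_schedule",
    "apply_reversal",
    "performance_trigger",
    "run_session",
]

#: display-only points mapping (never enters any likelihood)
WIN_POINTS = 100
LOSS_POINTS = -50


class ConfigError(ValueError):
    """Raised for an invalid task configuration."""


class AgentContractError(ValueError):
    """Raised when an agent returns an invalid choice-probability vector."""


@dataclass(frozen=True)
class TaskConfig:
    """Static definition of one PRL session.

    Trial indices are 1-based throughout: the contingency shift "at trial 81"
    means trial 81 is the first trial played under the post-shift set.
    """

    n_trials: int = 160
    n_options: int = 3
    probs_pre: tuple[float, ...] = (0.9, 0.5, 0.1)
    probs_post: tuple[float, ...] = (0.8, 0.4, 0.2)
    shift_trial: int = 81
    scheduled_period: int = 40
    perf_window: int = 10
    perf_criterion: int = 9

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.n_options < 1:
            raise ConfigError("n_options must be >= 1")
        for probs in (self.probs_pre, self.probs_post):
            if len(probs) != self.n_options:
                raise ConfigError(
                    "probability set length must equal n_options "
                    f"({len(probs)} != {self.n_options})"
                )
            if not all(0.0 <= p <= 1.0 for p in probs):
                raise ConfigError(f"probabilities must lie in [0, 1]: {probs}")
        if self.n_trials < self.shift_trial - 1:
            raise ConfigError("shift_trial may not exceed n_trials + 1")
        if self.shift_trial < 1:
            raise ConfigError("shift_trial must be >= 1")
        if self.perf_criterion > self.perf_window:
            raise ConfigError("perf_criterion must be <= perf_window")
        if self.scheduled_period < 1:
            raise ConfigError("scheduled_period must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One played trial: what was on offer, what was chosen, what happened."""

    t: int
    choice: int
    outcome: int
    assigned_probs: tuple[float, ...]
    reversal_event: str = "none"  # none | scheduled | performance

    @property
    def points(self) -> int:
        """Display-only points (win +100 / loss -50); never used in modelling."""
        return WIN_POINTS if self.outcome else LOSS_POINTS


@dataclass
class SessionData:
    """Ordered trial records for one participant."""

    participant_id: str
    records: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records, start=1):
            if rec.t != i:
                raise ValueError(f"records must be ordered 1..n with no gaps (saw t={rec.t} at position {i})")

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def choices(self) -> np.ndarray:
        return np.array([r.choice for r in self.records], dtype=int)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self.records], dtype=int)


@dataclass(frozen=True)
class Schedule:
    """Deterministic skeleton of a session: which probability set is active
    on each trial and where the scheduled (performance-independent)
    reversals fall."""

    active_sets: tuple[tuple[float, ...], ...]
    scheduled_reversals: tuple[int, ...]


def build_schedule(config: TaskConfig) -> Schedule:
    """Per-trial active probability set plus scheduled-reversal trials.

    Trials 1..shift_trial-1 run under ``probs_pre``; trials >= shift_trial
    under ``probs_post``. Scheduled reversals sit at multiples of
    ``scheduled_period`` (applied after that trial is played).
    """
    sets = tuple(
        config.probs_pre if t < config.shift_trial else config.probs_post
        for t in range(1, config.n_trials + 1)
    )
    reversals = tuple(
        t
        for t in range(config.scheduled_period, config.n_trials + 1, config.scheduled_period)
    )
    return Schedule(active_sets=sets, scheduled_reversals=reversals)


def apply_reversal(assignment: dict[int, float]) -> dict[int, float]:
    """Reverse a contingency assignment by swapping the best- and
    worst-probability options; middle options keep their probability.

    The swap is an involution: applying it twice restores the input.
    """
    new = dict(assignment)
    if len(new) < 2:
        return new
    best = max(new, key=new.__getitem__)
    worst = min(new, key=new.__getitem__)
    new[best], new[worst] = new[worst], new[best]
    return new


def performance_trigger(
    choice_history: Sequence[int], current_best: int, config: TaskConfig
) -> bool:
    """True iff the last ``perf_window`` choices (window must be full)
    contain at least ``perf_criterion`` picks of the current best option."""
    if len(choice_history) < config.perf_window:
        return False
    recent = choice_history[-config.perf_window :]
    return sum(c == current_best for c in recent) >= config.perf_criterion


class Agent(Protocol):
    """Choice-policy contract for the agent-environment loop.

    ``act`` returns choice probabilities over options 1..n (sum to 1);
    ``learn`` receives the played trial. ``next_probs`` exposes the
    assignment in effect for the following trial; learning agents ignore it,
    but oracle test agents may use it.
    """

    def act(self, t: int) -> Sequence[float]: ...

    def learn(self, record: TrialRecord, next_probs: dict[int, float]) -> None: ...


class UniformAgent:
    """Picks uniformly at random (the probabilities, not the sampling, are
    uniform; sampling happens in the environment loop)."""

    def __init__(self, n_options: int = 3) -> None:
        self.n_options = n_options

    def act(self, t: int) -> Sequence[float]:
        return [1.0 / self.n_options] * self.n_options

    def learn(self, record: TrialRecord, next_probs: dict[int, float]) -> None:
        pass


class FixedAgent:
    """Always picks one option."""

    def __init__(self, option: int, n_options: int = 3) -> None:
        self.option = option
        self.n_options = n_options

    def act(self, t: int) -> Sequence[float]:
        probs = [0.0] * self.n_options
        probs[self.option - 1] = 1.0
        return probs

    def learn(self, record: TrialRecord, next_probs: dict[int, float]) -> None:
        pass


class GreedyOracleAgent:
    """Test agent that always picks the currently best option (it reads the
    upcoming assignment from ``learn``, which real agents never do)."""

    def __init__(self, n_options: int = 3) -> None:
        self.n_options = n_options
        self._best: int | None = None

    def act(self, t: int) -> Sequence[float]:
        probs = [0.0] * self.n_options
        best = self._best if self._best is not None else 1
        probs[best - 1] = 1.0
        return probs

    def learn(self, record: TrialRecord, next_probs: dict[int, float]) -> None:
        self._best = max(next_probs, key=next_probs.__getitem__)


def _validate_probs(probs: Sequence[float], n_options: int) -> list[float]:
    p = [float(x) for x in probs]
    if len(p) != n_options:
        raise AgentContractError(
            f"agent returned {len(p)} probabilities for {n_options} options"
        )
    if any(x < 0 for x in p) or not math.isclose(sum(p), 1.0, abs_tol=1e-8):
        raise AgentContractError(f"invalid probability vector from agent: {p}")
    return p


def _rank_remap(
    assignment: dict[int, float], old_set: Sequence[float], new_set: Sequence[float]
) -> dict[int, float]:
    """Contingency shift: each option keeps its rank (0.9->0.8, 0.5->0.4,
    0.1->0.2), preserving option identity across the set change."""
    old_sorted = sorted(old_set, reverse=True)
    new_sorted = sorted(new_set, reverse=True)
    return {opt: new_sorted[old_sorted.index(p)] for opt, p in assignment.items()}


def run_session(
    agent: Agent,
    config: TaskConfig,
    seed: int | np.random.Generator,
    participant_id: str = "sim",
) -> SessionData:
    """Run one full agent-environment loop.

    Each trial: the shift re-maps probabilities if due, the agent's policy is
    sampled, the outcome is Bernoulli in the chosen option's assigned
    probability, the agent observes the trial, then reversal logic runs
    (scheduled reversal takes precedence over a coinciding performance
    trigger; either resets the performance window). Fully reproducible for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assignment = {j + 1: config.probs_pre[j] for j in range(config.n_options)}
    # pre-draw all uniforms so the trial loop is pure float arithmetic
    u_choice = rng.random(config.n_trials)
    u_outcome = rng.random(config.n_trials)

    records: list[TrialRecord] = []
    choices_since_reversal: list[int] = []
    for t in range(1, config.n_trials + 1):
        if t == config.shift_trial:
            assignment = _rank_remap(assignment, config.probs_pre, config.probs_post)

        probs = _validate_probs(agent.act(t), config.n_options)
        u = u_choice[t - 1]
        acc = 0.0
        choice = config.n_options
        for j, pj in enumerate(probs, start=1):
            acc += pj
            if u < acc:
                choice = j
                break
        outcome = int(u_outcome[t - 1] < assignment[choice])

        choices_since_reversal.append(choice)
        event = "none"
        best = max(assignment, key=assignment.__getitem__)
        if t % config.scheduled_period == 0:
            event = "scheduled"
        elif performance_trigger(choices_since_reversal, best, config):
            event = "performance"

        record = TrialRecord(
            t=t,
            choice=choice,
            outcome=outcome,
            assigned_probs=tuple(assignment[j + 1] for j in range(config.n_options)),
            reversal_event=event,
        )
        records.append(record)

        if event != "none":
            assignment = apply_reversal(assignment)
            choices_since_reversal = []
        agent.learn(record, assignment)

    return SessionData(participant_id=participant_id, records=records)
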