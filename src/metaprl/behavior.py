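"""Model-free behavioral statistics from PRL sessions.

The headline measure is the win-switch rate (WSR): of the trials on which a
participant was rewarded, the proportion followed by choosing a different
option on the next trial. Win-switching indexes behavioral instability —
changing course even when the environment just said "keep going".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prl import SessionData

__all__ = ["BehaviorSummary", "win_switch_rate", "performance"]


@dataclass(frozen=True)
class BehaviorSummary:
    """Win-switch counts and rate for one participant.

    ``wsr`` is None (missing, not an error) when the participant was never
    rewarded before the final trial, so the rate has an empty denominator.
    """

    participant_id: str
    n_win_trials: int
    n_win_switches: int
    performance: float

    @property
    def wsr(self) -> float | None:
        if self.n_win_trials == 0:
            return None
        return self.n_win_switches / self.n_win_trials


def win_switch_rate(session: SessionData) -> BehaviorSummary:
    """Win-switch rate over trials 1..n-1 (the final trial has no successor
    choice, so it cannot enter the denominator)."""
    if session.n_trials < 2:
        raise ValueError("need at least 2 trials for a win-switch rate")
    choices = session.choices
    outcomes = session.outcomes
    won = outcomes[:-1] == 1
    switched = choices[1:] != choices[:-1]
    n_win = int(won.sum())
    n_win_switch = int((won & switched).sum())
    return BehaviorSummary(
        participant_id=session.participant_id,
        n_win_trials=n_win,
        n_win_switches=n_win_switch,
        performance=performance(session),
    )


def performance(session: SessionData) -> float:
    """Mean reward rate over the whole session."""
    if session.n_trials == 0:
        raise ValueError("empty session")
    return float(np.mean(session.outcomes))
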