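"""Metacognition scoring of open-ended task reflections.

Participants answer two debrief questions about their strategy; the
concatenated text is scored on five metacognitive-prompting dimensions —
comprehension, judgement, evaluation, final decision, confidence — each as a
probability distribution over rubric levels 0..4, reduced to a continuous
expected-value score M_d = Σ P_i · i and averaged into M̄.

Scoring is delegated to a pluggable backend. Two ship here: a deterministic
rule-based scorer that maps surface features of the text (task vocabulary,
hypothesis talk, evaluative and decisional phrases, confidence markers) to
the five distributions, and an LLM-prompt backend that builds the structured
scoring prompt and parses the JSON reply through an injected transport
callable. Reflections too short to evaluate bypass the backend entirely and
score 0.0 on every dimension.

Also here: the verbosity covariate (character count), CRT scoring with
lenient answer normalisation, the general-cognition composite, and
two-way random-effects intraclass correlations for rater reliability.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = [
    "DIMENSIONS",
    "Reflection",
    "ScoreDistribution",
    "MPScores",
    "CognitionInputs",
    "BackendContractError",
    "ScorerBackend",
    "MockScorer",
    "PromptScorer",
    "score_reflection",
    "expected_score",
    "mean_mp",
    "score_crt",
    "general_cognition",
    "ICCResult",
    "icc",
    "SHORT_TEXT_THRESHOLD",
]

DIMENSIONS = ("comprehension", "judgement", "evaluation", "final_decision", "confidence")

#: reflections with fewer non-whitespace characters than this are auto-scored 0
SHORT_TEXT_THRESHOLD = 10

_LEVELS = np.arange(5, dtype=float)


class BackendContractError(ValueError):
    """A scorer backend returned malformed probability vectors."""


@dataclass(frozen=True)
class Reflection:
    """One participant's combined debrief answer."""

    participant_id: str
    text: str

    @property
    def char_count(self) -> int:
        """Verbosity: raw character count of the combined response."""
        return len(self.text)


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability distribution over rubric levels 0..4 for one dimension."""

    dimension: str
    probs: tuple[float, float, float, float, float]
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if len(self.probs) != 5 or any(p < 0 for p in self.probs):
            raise ValueError("probs must be five non-negative values")
        if abs(sum(self.probs) - 1.0) > 1e-6:
            raise ValueError(f"probs must sum to 1 (got {sum(self.probs)})")


@dataclass(frozen=True)
class MPScores:
    """Per-dimension expected scores and their mean."""

    m_d: dict[str, float]

    @property
    def m_bar(self) -> float:
        return sum(self.m_d.values()) / len(self.m_d)


def expected_score(dist: ScoreDistribution) -> float:
    """Expected value of the rubric distribution: M_d = Σ P_i · i ∈ [0, 4]."""
    return float(np.dot(dist.probs, _LEVELS))


def mean_mp(scores: Sequence[float]) -> float:
    """M̄: arithmetic mean of the five dimension scores."""
    if len(scores) != len(DIMENSIONS):
        raise ValueError(f"expected {len(DIMENSIONS)} dimension scores, got {len(scores)}")
    if any(not (0.0 <= s <= 4.0) for s in scores):
        raise ValueError("dimension scores must lie in [0, 4]")
    return float(np.mean(scores))


class ScorerBackend(Protocol):
    """Maps reflection text to five rubric distributions (one per dimension,
    in DIMENSIONS order)."""

    def score(self, text: str) -> Sequence[Sequence[float]]: ...


# --- deterministic rule-based mock backend ----------------------------------

_FEATURES: dict[str, tuple[str, ...]] = {
    # task-content vocabulary: did they describe what the task was about?
    "comprehension": (
        "deck", "card", "avatar", "partner", "option", "reward", "point",
        "task", "game", "trial", "choice", "choos", "pick",
    ),
    # hypothesis formation / pattern talk
    "judgement": (
        "pattern", "notice", "seem", "count", "track", "at first", "figure",
        "test", "expect", "wonder", "thought that", "theory",
    ),
    # evaluating how strategies fared
    "evaluation": (
        "work", "better", "worse", "fail", "improve", "did not help",
        "didn't help", "paid off", "mistake", "compar",
    ),
    # settled rules / final strategies
    "final_decision": (
        "decide", "stuck with", "stick", "rule", "strategy", "settle",
        "always", "until", "ended up", "in the end", "would switch",
    ),
    # confidence and uncertainty talk
    "confidence": (
        "confident", "sure", "guess", "unsure", "risk", "certain", "doubt",
        "mostly", "probably", "safe", "lucky",
    ),
}


class MockScorer:
    """Deterministic rule-based scorer used throughout the test suite.

    Counts distinct feature markers per dimension (capped at 4) and returns a
    near-point-mass distribution at that level. Pure function of the text:
    identical input gives identical output, and adding a marker-bearing
    clause can only raise levels (monotone by construction).
    """

    def __init__(self, mass: float = 0.85) -> None:
        if not 0.5 < mass <= 1.0:
            raise ValueError("mass must be in (0.5, 1]")
        self.mass = mass

    def level(self, text: str, dimension: str) -> int:
        low = text.lower()
        hits = sum(1 for marker in _FEATURES[dimension] if marker in low)
        return min(4, hits)

    def score(self, text: str) -> list[list[float]]:
        out = []
        spread = 1.0 - self.mass
        for dim in DIMENSIONS:
            lev = self.level(text, dim)
            probs = [0.0] * 5
            probs[lev] = self.mass
            # symmetric spill to neighbours; edge levels spill one-sided
            neighbours = [i for i in (lev - 1, lev + 1) if 0 <= i <= 4]
            for i in neighbours:
                probs[i] += spread / len(neighbours)
            out.append(probs)
        return out


# --- LLM prompt backend ------------------------------------------------------

_PROMPT_TEMPLATE = """You are a metacognitive scientist rating the structure of a participant's \
reflection on a three-option probabilistic reward learning task.

Rate the reflection on five dimensions: comprehension, judgement, evaluation,
final_decision, confidence. For each dimension return a probability
distribution over the integer scores 0-4 (five probabilities summing to 1),
allowing uncertainty in borderline cases. Recognise subtle or abstract forms
of insight (counterfactual reasoning, conditional logic, philosophical
restraint). Reply with JSON only, of the form:
{{"comprehension": [p0,p1,p2,p3,p4], "judgement": [...], "evaluation": [...],
  "final_decision": [...], "confidence": [...], "rationale": "..."}}

Reflection:
\"\"\"{text}\"\"\"
"""


class PromptScorer:
    """Backend that builds the structured scoring prompt and parses the JSON
    reply. The actual model call is an injected ``transport`` callable
    (prompt -> raw reply), to be bound to a temperature-0 chat-completion
    endpoint by the user; no network client is bundled."""

    def __init__(self, transport: Callable[[str], str] | None = None) -> None:
        self.transport = transport

    def build_prompt(self, text: str) -> str:
        return _PROMPT_TEMPLATE.format(text=text)

    def score(self, text: str) -> list[list[float]]:
        if self.transport is None:
            raise RuntimeError(
                "PromptScorer needs a transport callable (prompt -> reply); "
                "use MockScorer for fully offline scoring"
            )
        reply = self.transport(self.build_prompt(text))
        payload = json.loads(reply)
        try:
            return [[float(p) for p in payload[dim]] for dim in DIMENSIONS]
        except (KeyError, TypeError, ValueError) as exc:
            raise BackendContractError(f"malformed backend reply: {exc}") from exc


# --- scoring entry point -----------------------------------------------------

def score_reflection(
    reflection: Reflection,
    backend: ScorerBackend,
    short_threshold: int = SHORT_TEXT_THRESHOLD,
) -> list[ScoreDistribution]:
    """Score one reflection on all five dimensions.

    Texts with fewer than ``short_threshold`` non-whitespace characters are
    too short to evaluate and bypass the backend: every dimension gets a
    point mass at 0 (so M_d = 0.0). Backend vectors off by at most 1e-3 from
    unit mass are renormalised; anything worse is a contract error.
    """
    stripped = re.sub(r"\s", "", reflection.text)
    if len(stripped) < short_threshold:
        return [
            ScoreDistribution(dimension=dim, probs=(1.0, 0.0, 0.0, 0.0, 0.0))
            for dim in DIMENSIONS
        ]
    raw = backend.score(reflection.text)
    if len(raw) != len(DIMENSIONS):
        raise BackendContractError(f"backend returned {len(raw)} distributions, need 5")
    dists = []
    for dim, probs in zip(DIMENSIONS, raw):
        probs = [float(p) for p in probs]
        if len(probs) != 5 or any(p < 0 for p in probs):
            raise BackendContractError(f"invalid probability vector for {dim}: {probs}")
        total = sum(probs)
        if abs(total - 1.0) > 1e-3:
            raise BackendContractError(
                f"probabilities for {dim} sum to {total}, beyond renormalisation tolerance"
            )
        probs = [p / total for p in probs]
        dists.append(ScoreDistribution(dimension=dim, probs=tuple(probs)))
    return dists


def scores_from_distributions(dists: Sequence[ScoreDistribution]) -> MPScores:
    """Reduce the five distributions to expected-value scores."""
    return MPScores(m_d={d.dimension: expected_score(d) for d in dists})


# --- CRT and general cognition ----------------------------------------------

_WORD_NUMBERS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "twenty": 20, "twenty four": 24, "twenty-four": 24,
    "forty seven": 47, "forty-seven": 47, "hundred": 100, "one hundred": 100,
}


def _parse_answer(answer: str) -> tuple[float | None, str]:
    """Extract (numeric value, unit hint) from a free-text CRT answer."""
    low = answer.lower().strip()
    unit = ""
    if re.search(r"cent|¢|penn", low):
        unit = "cents"
    elif re.search(r"dollar|\$", low):
        unit = "dollars"
    elif re.search(r"\bsec", low):
        unit = "seconds"
    elif re.search(r"\bmin", low):
        unit = "minutes"
    elif re.search(r"\bhour|\bhr", low):
        unit = "hours"
    elif re.search(r"\bday", low):
        unit = "days"
    m = re.search(r"[-+]?\d*\.?\d+", low.replace(",", ""))
    if m:
        return float(m.group()), unit
    for phrase in sorted(_WORD_NUMBERS, key=len, reverse=True):
        if re.search(rf"\b{phrase}\b", low):
            return float(_WORD_NUMBERS[phrase]), unit
    return None, unit


def _crt_item1(answer: str) -> int:
    """Bat and ball: the ball costs 5 cents ($0.05)."""
    value, unit = _parse_answer(answer)
    if value is None:
        return 0
    if unit == "dollars":
        return int(math.isclose(value, 0.05))
    if unit == "cents":
        return int(math.isclose(value, 5.0))
    # unitless: accept either the cent (5) or dollar (0.05) form
    return int(math.isclose(value, 5.0) or math.isclose(value, 0.05))


def _crt_item2(answer: str) -> int:
    """Widget machines: 5 minutes."""
    value, unit = _parse_answer(answer)
    if value is None:
        return 0
    if unit == "seconds":
        return int(math.isclose(value, 300.0))
    if unit == "hours":
        return int(math.isclose(value, 5.0 / 60.0))
    return int(math.isclose(value, 5.0))


def _crt_item3(answer: str) -> int:
    """Lily pads: 47 days."""
    value, _ = _parse_answer(answer)
    return int(value is not None and math.isclose(value, 47.0))


def score_crt(answers: Sequence[str]) -> tuple[tuple[int, int, int], float]:
    """Score the three cognitive-reflection items leniently.

    Accepts numeric, word and unit-bearing variants ("five", "5 minutes",
    "0.05"); anything unparseable scores 0. Returns per-item 0/1 marks and
    their mean accuracy in {0, 1/3, 2/3, 1}.
    """
    if len(answers) != 3:
        raise ValueError("CRT has exactly three items")
    marks = (_crt_item1(answers[0]), _crt_item2(answers[1]), _crt_item3(answers[2]))
    return marks, sum(marks) / 3.0


@dataclass(frozen=True)
class CognitionInputs:
    """Education (1-8 ordinal) and CRT accuracy feeding the composite."""

    education: int
    crt_accuracy: float

    def __post_init__(self) -> None:
        if self.education not in range(1, 9):
            raise ValueError("education must be an integer 1..8")
        if not 0.0 <= self.crt_accuracy <= 1.0:
            raise ValueError("crt_accuracy must lie in [0, 1]")


def general_cognition(inputs: CognitionInputs) -> float:
    """General-cognition composite: the literal average of the 1-8 education
    level and 0-1 CRT accuracy. The two scales are deliberately not
    rescaled before averaging; the composite is z-scored before entering
    any model, so only its ordering matters downstream."""
    return (inputs.education + inputs.crt_accuracy) / 2.0


# --- rater reliability --------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    value: float
    form: str
    defined: bool


def icc(ratings: np.ndarray, form: str = "single") -> ICCResult:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    ``ratings`` is subjects x raters (complete). ``form="single"`` gives
    ICC(2,1) (reliability of one rater); ``form="average"`` gives ICC(2,k)
    (reliability of the k-rater mean). A constant table has no
    between-subject variance to apportion, so the ICC is undefined and
    flagged rather than raised.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("need a complete subjects x raters table, >= 2 each")
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    if np.allclose(ratings, ratings.flat[0]):
        return ICCResult(value=float("nan"), form=form, defined=False)
    n_subj, n_raters = ratings.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subj),
            "score": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    key = "ICC(A,1)" if form == "single" else "ICC(A,k)"  # two-way random, absolute agreement
    value = float(table.loc[key, "ICC"])
    return ICCResult(value=value, form=form, defined=bool(np.isfinite(value)))
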