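"""Score open-ended task reflections on the five metacognition dimensions.

Uses the deterministic rule-based scorer. Each dimension gets a probability
distribution over rubric levels 0-4; the expected value M_d is the
continuous score and M-bar is their mean. A near-empty reflection trips the
auto-zero rule.
"""

from metaprl import MockScorer, Reflection, score_reflection
from metaprl.metacog import scores_from_distributions

rich = Reflection(
    "p01",
    "Each deck gave a reward only some of the time. I noticed a pattern and "
    "counted how long streaks ran. Jumping around was worse than being "
    "patient. In the end I kept a rule and stuck with a winner till it went "
    "cold. Mostly it was a guess and I took a risk now and then.",
)
terse = Reflection("p02", "no")

backend = MockScorer()
for ref in (rich, terse):
    dists = score_reflection(ref, backend)
    scores = scores_from_distributions(dists)
    print(f"--- {ref.participant_id} (verbosity {ref.char_count} chars)")
    for dim, m_d in scores.m_d.items():
        print(f"  {dim:>14}: M_d = {m_d:.2f}")
    print(f"  {'M-bar':>14}: {scores.m_bar:.2f}  (0 = no reflective structure, 4 = ceiling)")
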