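# Methods

## Task environment

The PRL task is a 3-armed bandit with binary feedback. Defaults: 160
trials; reward probabilities 0.9/0.5/0.1 until trial 80 and 0.8/0.4/0.2
from trial 81 (the *shift*, which re-maps each option to the same rank in
the new set, preserving option identity); performance-independent reversals
after trials 40, 80, 120, 160; a performance-dependent reversal whenever at
least 9 of the last 10 choices picked the currently best option. Trial
indices are 1-based.

Design choices where the protocol is under-determined:

- **Reversal mechanism**: the best- and worst-probability options swap;
  the middle option keeps its probability. The swap is an involution.
- **Refractory window**: after any reversal the performance window resets,
  so a performance trigger can never fire within `perf_window` trials of
  the previous reversal. If a scheduled reversal and a performance trigger
  coincide, a single reversal labelled `scheduled` is applied.
- The shift is not a reversal and does not reset the window.
- The final-trial scheduled reversal (t=160) is emitted but has no
  behavioral consequence.
- Outcomes are 0/1 in all modelling; the ±points mapping (win +100,
  loss −50) exists only for display.

## Perceptual model

Three-level HGF for multi-armed binary bandits with AR(1) (mean-reverting)
latent dynamics. Level 2 tracks each option's reward log-odds; level 3
tracks log-volatility. Per trial, with chosen option c and outcome y:

```
x̂2_j = μ2_j + φ2 (m2 − μ2_j)            x̂3 = μ3 + φ3 (m3 − μ3)
σ̂2_j = σ2_j + exp(κ x̂3 + ω)            σ̂3 = σ3 + θ
m̂_j  = sigmoid(x̂2_j)

δ1 = y − m̂_c
π2 = 1/σ̂2_c + m̂_c(1 − m̂_c)            μ2_c = x̂2_c + δ1/π2 ; σ2_c = 1/π2
w2 = exp(κ x̂3 + ω)/σ̂2_c
δ2 = (σ2_c + (μ2_c − x̂2_c)²)/σ̂2_c − 1
π3 = 1/σ̂3 + ½κ² w2 (w2 + (2w2 − 1) δ2)  μ3 = x̂3 + ½κ w2 δ2/π3 ; σ3 = 1/π3
```

Unchosen options only drift and diffuse. A non-positive posterior precision
raises an instability error carrying the trial index (inside the optimiser
it becomes a large penalty instead). The phasic-volatility exponent
κx̂3 + ω is capped at 30 before exponentiation; beyond that the filter is in
a degenerate runaway regime and the cap only prevents floating-point
overflow. The sigmoid saturates at |x| = 40 for the same reason.

The implementation is pinned to exactly these equations by a test-suite
oracle: an independently coded, straight-line numpy re-implementation must
agree to 1e-10 on short random sessions.

## Response model

Choice probabilities are a softmax over the predicted reward probabilities
m̂ with inverse temperature β(t) = exp(−x̂3(t)): decision noise grows with
currently inferred volatility. The sign convention (noise *increasing* in
volatility) is a design choice; the opposite convention would flip the
μ₃⁰→WSR mapping direction. β uses the pre-outcome prediction, so a choice
never conditions on the outcome it produces. The softmax is computed
max-shifted and is safe at extreme β.

## Parameters, priors, fitting

| parameter | meaning | default | estimation space |
|---|---|---|---|
| μ₃⁰ | initial volatility prior | −2.6 (free, prior var 1) | identity |
| σ₃⁰, σ₂⁰ | initial variances | 1.0 | log |
| κ | volatility→learning coupling | 0.2 | log |
| ω | tonic level-2 log-volatility | −0.5 | identity |
| θ | level-3 innovation variance | 0.1 | log |
| φ2, φ3 | AR(1) reversion rates | 0.05 | logit |
| m2 | level-2 attractor | 0 | identity |
| m3 | level-3 attractor | tied to μ₃⁰ | — |

Priors live in `src/metaprl/data/default_priors.yaml` (estimation-space
mean and variance per parameter; zero variance = fixed). Only μ₃⁰ is free
by default; with `tie_m3` the level-3 attractor follows μ₃⁰, the usual
convention for mean-reverting configurations, which also makes μ₃⁰ a
persistent individual trait rather than a transient initial condition.
Whether mean reversion acts at level 2, level 3 or both is controlled
entirely by fixing or freeing φ2/φ3 through the prior file.

MAP fitting maximises Σ_t log P(choice_t) plus Gaussian log-priors over the
free parameters in the unbounded estimation space, by BFGS from
`n_restarts` starts (first at the prior mean, the rest jittered by the
prior SD); best log-joint wins, ties to first found. Unstable evaluations
score a 1e12 penalty. With every parameter fixed the prior means and their
log-joint are returned without optimisation.

The default dynamics (κ = 0.2, ω = −0.5) were chosen so that (a) the
learning rate is fast enough for exploiting agents to track reversals, and
(b) μ₃⁰ acts on behavior mainly through decision noise rather than through
learning speed. With a strong κ the two channels cancel — faster learning
compensates the extra choice noise — and win-switching stops being
maladaptive, contrary to the empirical picture this model family is used
for. Small κ also keeps w2 in the regime where the level-3 precision update
cannot go negative in ordinary sessions.

## Behavioral statistics

WSR = (rewarded trials among t = 1..n−1 followed by a different choice at
t+1) / (rewarded trials among t = 1..n−1). The final trial has no successor
and is excluded from the denominator; a session with an empty denominator
yields a missing value, not an error. Performance is the mean outcome.
Lose-stay and other model-free metrics are deliberately out of scope.

## Metacognition scoring

Reflections are scored per dimension as a probability distribution over
rubric levels 0–4; M_d is its expectation and M̄ the mean over the five
dimensions. Texts with fewer than 10 non-whitespace characters (config-
urable) bypass the backend and score 0.0 everywhere. Backend vectors whose
mass is off by ≤ 1e−3 are renormalised; worse is a contract error.

Two backends:

- **MockScorer** (used by all tests): counts distinct feature markers per
  dimension (task vocabulary, hypothesis talk, evaluative phrases,
  decisional phrases, confidence markers), caps at 4, and returns a
  near-point-mass distribution. Deterministic and monotone: adding a
  marker-bearing clause can only raise scores.
- **PromptScorer**: builds the structured scoring prompt and parses a JSON
  reply through an injected transport callable (to be bound to a
  temperature-0 chat endpoint by the user). No network client is bundled,
  and no test depends on one.

Verbosity is the raw character count. CRT answers are scored leniently
(numeric, word and unit variants; unparseable → 0). The general-cognition
composite is the literal average of the 1–8 education level and 0–1 CRT
accuracy; the scales are intentionally not aligned because the composite is
z-scored before entering any model — only its ordering matters. ICC(2,1)
and ICC(2,k) are two-way random-effects absolute-agreement coefficients
(pingouin's ICC(A,1)/ICC(A,k)); a constant ratings table is flagged
undefined rather than raised.

## Moderation analysis

Each participant contributes binomial counts (win-switches, win trials), so
subjects are weighted by the information they carry; participants with zero
win trials are excluded and counted. All regressors are z-scored (sample
SD). The full model is
`WSR ~ z(μ₃⁰) * z(M̄) + z(verbosity) + z(cognition)` with logit link; the
interaction is tested by LRT against the nested model. Effects are reported
as exp-coefficients with Wald CIs and as average marginal effects
(mean of β·p(1−p); the AME of a term is the derivative along its own design
column — the interaction column is a separate regressor).

Probability-scale contrasts evaluate predicted switching at the four
(z(μ₃⁰), z(M̄)) ∈ {−1, +1}² grid points with controls at 0, and report the
−1→+1 SD rise at low and high M̄ in percentage points. Because the logistic
curve bends near 0, these can differ even when β₃ = 0 — which is why the
contrast, not only the link-scale interaction, is reported. The bootstrap
resamples participants with replacement (1,000 iterations by default),
refits the full model, and takes percentile 95% CIs for Δ = pp_high −
pp_low. The z-scored design stays anchored to the observed table so the
±1 SD grid means the same thing in every iterate; more than 5% failed
refits aborts with a diagnostic. The Breusch–Pagan diagnostic (LM = n·R² of
the squared-residual auxiliary regression, plus the companion F form)
documents the mean-variance coupling that motivates the binomial GLM over
OLS; a numerically perfect OLS fit returns statistic 0.

Group comparisons use Welch t (two groups; Cohen's d from the pooled SD)
or Welch one-way ANOVA (more levels).

## Simulation experiments

**Parameter recovery**: each participant's parameters are treated as ground
truth; 3 full closed-loop sessions are simulated per participant, refit
with identical priors, and recovery is summarised by the Pearson r between
true and recovered values per free parameter (one-sided p for r > 0).
Failed refits are recorded, excluded from the correlation and counted.
Zero truth variance flags the correlation undefined.

**Belief→behavior mapping**: holding each participant's other parameters
fixed, μ₃⁰ sweeps a 15-point grid spanning the empirical 15th–85th
percentiles (linear interpolation between order statistics); 100 sessions
per grid point are simulated and their WSRs averaged into a subject-level
curve (sessions with no rewarded trials are skipped). Curves are averaged
over participants and within low/high metacognition groups (±1 SD of
z-scored M̄; mid-range participants are discarded and the retained group
sizes reported). The slope difference is tested by OLS on the two
group-mean 15-point curves with a group interaction — participant-level
clustering is deliberately ignored to keep the test at the level of the
group-mean curves.

## Synthetic cohort

The generator emulates the study population: 486 participants, 99 above
the persecution cutoff (≥ 11 on a zero-inflated 0–40 score where only the
cutoff relation matters). The high-paranoia group carries a +0.63 pooled-SD
shift in μ₃⁰ and a −0.73 SD shift in the latent metacognitive-structure
trait (discretised to levels 0–4, which drive the reflection templates, so
reflections are also shorter in that group). Education, CRT accuracy, age
and gender are generated without group effects.

The μ₃⁰ population base, N(−2.6, 1.0), was calibrated so the simulated
win-switch distribution matches the reported empirical summary for this
task family (min 0, median ≈ 0.02, q3 ≈ 0.1, mean ≈ 0.1, strongly
right-skewed) — the generated default cohort lands at median ≈ 0.02–0.04
and q3 ≈ 0.1.

Two structural commitments:

- **The WSR gap is emergent.** Sessions are simulated by HGF agents from
  each participant's parameters; nothing injects switching directly, so the
  group difference in WSR exists only because the μ₃⁰ difference propagates
  through the model.
- **Metacognitive gating.** A participant's *enacted* volatility prior is
  `base + (1 − a·level/4)·(μ₃_belief − base)` with a = 0.6 by default: the
  more structured the reflection, the less a deviant belief is expressed in
  behavior. The analysis only ever sees the belief value. Setting a = 0
  disables the interaction; the effect-size targets set to 0 produce null
  cohorts on which the group tests are calibrated.

Reflection templates carry exactly `level` feature markers per dimension,
so the rule-based scorer reads the built level back; marker-free filler
sentences add verbosity variation that is independent of structure (without
it, verbosity and M̄ would be collinear and the regression could not
separate them — they remain strongly correlated, as in real data).

What the synthetic cohort does **not** emulate: real reflection language
(templates are detectable as such and are labelled synthetic), item-level
questionnaire structure, demographic effects, reaction times, and any
coupling between cognition/education and task behavior. Passing tests on
this cohort show that the pipeline recovers structure that is truly
present; they cannot certify effect sizes in human data.

## Problem sizes and determinism

Protocol-scale checks run at 40 synthetic participants (recovery: 3
repetitions each; mapping: 15 grid points × 100 repetitions), and the
inference calibration uses 200–500 simulated datasets per property, sizes
chosen to keep the full suite comfortably fast while leaving the Monte
Carlo error well below the tested margins. Every stochastic routine takes
a seed or Generator; the CLI derives per-stage child seeds from one global
seed, so stages rerun independently yet reproducibly.

## Known limitations

- Only μ₃⁰ is free in the default priors; freeing several parameters at
  once is supported but recovery was validated for μ₃⁰ (the quantity the
  analysis consumes).
- The supplementary prior table of the original model configuration is not
  bundled; users replicating a specific dataset should edit the prior YAML.
- The LLM scoring backend is an interface, not a replication: scores from a
  live model will differ from the rule-based mock.
- The binomial GLM treats win-trial counts as fixed denominators;
  overdispersion is not modelled.
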