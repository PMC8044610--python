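# Methods

## The measurement model

Both tasks are yes/no decisions modelled with equal-variance Gaussian
signal detection theory. On trial *i* the observer holds a scalar
evidence value drawn from N(0, 1) when the signal is absent (Sᵢ = 0) and
from N(d′, 1) when it is present (Sᵢ = 1), and responds "signal" when the
evidence exceeds a criterion. Parameterized by sensitivity d′ and bias
c, the probability of a signal response is

    pᵢ = (1 − Sᵢ)·[1 − Φ(c + d′/2)] + Sᵢ·[1 − Φ(c − d′/2)],

and each response yᵢ ~ Bernoulli(pᵢ), independently across trials. For
detection, "signal" means any reflector position and the response is
yes/no; for localization the *left* reflector is arbitrarily coded as
signal and the response left/right. d′ is unconstrained in sign — an
observer who systematically responds against the stimulus has d′ < 0 —
and c < 0 means yes-leaning (liberal), c > 0 no-leaning (conservative).

Given interior hit and false-alarm proportions the closed forms
d′ = Φ⁻¹(H) − Φ⁻¹(F), c = −(Φ⁻¹(H) + Φ⁻¹(F))/2 invert this model
exactly. At H or F of exactly 0 or 1 they diverge; `echosdt` raises a
typed error there rather than applying a continuity correction, because
the package's own remedy is the Bayesian estimator, whose prior keeps
the posterior proper (an all-yes cell gets a large but finite d′ with a
wide interval). Φ and Φ⁻¹ are scipy's `ndtr`/`ndtri` (relative error
well below 1e−10); the test suite checks them against an independent
bisection-on-quadrature probit.

## The two Bayesian models

Fitted per participant to the trial-level 0/1 responses, with
independent Normal(0, 3) priors on every parameter — weakly informative
on the probit scale, where |d′| > 6 is already near-ceiling behavior.

* **Categorical model.** A separate (d′, c) pair per task × distance
  cell: 2 × 10 × 2 = 40 parameters under the default design. Because
  trials are conditionally independent, the posterior factorizes over
  cells; each cell is sampled as an independent 2-D problem with its
  binomial sufficient statistics (n and yes-counts on signal and noise
  trials). This is exact, not an approximation.
* **Exponential model.** d′ changes by a fixed proportion per meter:
  d′(X) = α₀·exp(α₁·X) for detection and β₀·exp(β₁·X) for localization,
  with one distance-constant bias per task (c₀, c₁): 6 parameters fit
  jointly. Distance enters in raw meters (no centering), so the
  amplitude is the d′ extrapolated to X = 0 — outside the 1.00–4.25 m
  design range, which is why its posterior is the widest.

Point estimates are posterior medians; intervals are 95%
highest-posterior-density (HPD) intervals, computed as the narrowest
window of ⌈0.95·n⌉ consecutive sorted draws (ties broken by the first
minimal window; at least 100 draws required). Derived quantities — the
per-distance detection-minus-localization d′ contrast, the
categorical model's per-task mean bias, between-task bias differences —
are always computed draw-wise before summarising, never from summaries.

### Sampling and diagnostics

Posteriors are sampled with the affine-invariant ensemble sampler
(emcee), using a 0.8/0.2 mixture of differential-evolution and snooker
moves, which mix far better than the default stretch move on these
correlated low-dimensional posteriors. Walkers start in a tight ball
(sd 0.05) around the smoothed closed-form estimate (categorical cells)
or a Nelder-Mead posterior mode (exponential model). Defaults: 16
walkers × 1,200 post-warmup draws after 500 warmup steps per cell for
the categorical model, and 16 × 4,000 after 1,000 for the exponential
model — sized so a full two-model participant fit takes tens of seconds
on one CPU while clearing split-R̂ ≤ 1.01 and bulk ESS ≥ 400 on every
parameter (walkers play the role of chains in both diagnostics, via
arviz). A fit missing either threshold is returned flagged
(`converged=False`) and logged, never silently accepted. Bernoulli
probabilities are clamped to [1e−12, 1 − 1e−12] inside the
log-likelihood; the clamp cannot bind at prior-plausible parameters.
Every fit is bit-reproducible from its seed; per-cell seeds are derived
from the config seed, participant id and cell index through a
`SeedSequence`, so results do not depend on fit order.

## The synthetic experiment

The generator reproduces the trial structure the estimators assume: per
session, each design distance appears exactly
`reps_per_distance_per_session` times in a uniformly shuffled order
(method of constant stimuli); the reflector position is drawn i.i.d. per
trial from the task's stimulus probabilities — (0.25, 0.25, 0.5) for
left/right/none in detection, (0.5, 0.5) in localization — with no
counterbalancing constraint, since none is part of the design being
emulated. Defaults: 10 distances 1.00–4.25 m, 4 days × 10 sessions × 50
trials per task, day 1 practice and excluded from analysis, leaving 150
trials per distance × task and 3,000 analysis responses per participant.

Responses are drawn from exactly the observation model above, with the
observer's truth either categorical (arbitrary d′ per cell) or
exponential in distance. An optional lapse rate λ mixes in
stimulus-independent guessing (p → λ/2 + (1 − λ)p); it is **off by
default** because the fitted model contains no lapse parameter — turning
it on is the intended way to study misspecification. A single root seed
is expanded deterministically per (participant, task, day, session) and
per purpose (scheduling vs response draws), so any subset of the
experiment regenerates identically in isolation.

What the simulator does *not* emulate: acoustics (masking, reverberation,
interaural cues), learning or fatigue across days and sessions, serial
dependence between trials, and response omissions. Passing parameter-
recovery tests therefore certifies the estimation machinery under the
model's own assumptions — it does not certify the model against real
listeners, whose day-to-day drift and lapses are outside it.

The default simulated observer (α₀ = 3, α₁ = −0.4, β₀ = 2, β₁ = −0.6,
c₀ = 0.1, c₁ = −0.2) is a moderately sensitive listener whose detection
advantage over localization shrinks with distance and whose biases are
small and opposite in sign across tasks — the typical qualitative
pattern for this paradigm.

## Group-level ANOVA

The 2 (task) × 10 (distance) repeated-measures ANOVA operates on the
complete participants × tasks × distances grid of categorical-model d′
medians. The classical fully-within decomposition is used: each effect
is tested against its own effect-by-subject interaction, with partial
η² = SS_effect/(SS_effect + SS_error) and uncorrected degrees of freedom
(1, n−1), (9, 9(n−1)), (9, 9(n−1)) — no sphericity correction is
applied, by design. F-distribution tail p-values are reported as a
convenience. Zero error variance (e.g. an exactly additive grid) raises
rather than returning an infinite F. Excluding a participant for a
sensitivity re-analysis is a caller-side filter on the grid.

## Echo-delay geometry

With speaker, ears and disk collinear, the delay between the direct
click and its reflection is 2·(ear_to_disk − ear_to_speaker)/v, i.e. a
slope of 2000/v ms per meter of disk distance: 5.8 ms/m at the default
v = 343 m/s (dry air, 20 °C; rounding to one decimal makes the figure
robust across 340–346 m/s). The real apparatus offsets the disks 18°
laterally; the collinear idealization ignores this (< 5% path-length
error) and is intentionally a geometry sanity check, not an acoustic
model — measured intercepts depend on the exact speaker placement and
are out of scope.

## Problem sizes in the shipped checks

The test suite exercises reduced designs (2–3 distances, 1 analysis day)
for most sampler tests, the full 10-distance design for the
parameter-recovery study (20 replicate simulated participants at
slightly shortened chains: 16 × 1,000 draws) and for the closed-form
equivalence check (10,000 trials per cell), and 10⁶ draws for HPD
calibration. These sizes were chosen as the smallest at which each
property is sharply testable.

## Known limitations

* The sampler is ensemble MCMC, not Hamiltonian; for the 6-parameter
  model this costs some efficiency but the posteriors here are smooth,
  low-dimensional and unimodal in practice.
* The exponential model's amplitude parameters extrapolate to X = 0 and
  are weakly identified when sensitivity is near zero across the range
  (amplitude × rate trade-off); expect wide, skewed posteriors there.
* With very few trials per cell (≲ 10) the categorical posteriors are
  prior-dominated; the single-trial behavior is characterized exactly in
  the tests via grid integration.
* No hierarchical pooling across participants: each listener is fitted
  independently, matching the per-individual analysis the package
  implements; a multilevel extension would change the estimands.
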