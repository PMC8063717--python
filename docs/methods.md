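# Methods

## The task being modeled

Each trial of the main task has two stages.  At the *metacognitive
judgment* stage the observer chooses between an internal probability
option — an RDK whose motion coherence `c ∈ {0, .03, .06, .12, .25, .37,
.50, .75}` determines how likely the observer is to discriminate its
motion direction correctly — and an external probability option, a fully
coherent RDK whose dot count advertises a reward probability `p_ext ∈
{.1, .3, .5, .6, .7, .8, .9, 1.0}`.  At the *perceptual decision* stage
the chosen stimulus reappears (rotated, so the earlier viewing cannot be
reused as a direction percept) and the observer reports left or right.
A correct response is rewarded with certainty for the internal option
and with probability `p_ext` for the external one; an incorrect response
is never rewarded.  Sessions present a balanced, shuffled cross of the
8×8 offer grid; the canonical session length is 195 trials (three full
grid passes plus a truncated fourth).  A *follow-up* session of the same
stimuli without the choice stage estimates the observer's baseline
accuracy per coherence — the empirical internal-probability table that
every downstream analysis conditions on.

## Generative observer

Per trial with offer `(c, p_ext)`:

1. **Evidence.** A signed evidence sample `e ~ Normal(c, σ_e)` is drawn,
   oriented toward the true direction.  The psychometric accuracy curve
   is Weibull, `acc(s) = 0.5 + (0.5 − λ/2)(1 − exp(−(s/α)^β))`, chance
   anchored at zero coherence.  The per-trial probability of a correct
   response is `acc(|e|)` when `e ≥ 0` and `1 − acc(|e|)` otherwise, so
   marginal accuracy at `c = 0` is exactly one half and approaches the
   Weibull curve as `σ_e → 0`.
2. **Metacognitive readout and choice.** The observer reads the evidence
   strength through the same curve, `p̂_int = acc(min(|e|, 1))`, distorts
   both probabilities with the weighting function `w(·; γ)`, and chooses
   the internal option with probability
   `sigmoid(β_choice · [w(p̂_int; γ_int) − w(p_ext; γ_ext)] + σ_m · z)`,
   `z ~ Normal(0,1)`.
3. **Outcome.** If internal was chosen the *same* `e` drives the
   perceptual outcome; external perceptual decisions are correct with a
   fixed ceiling probability of 0.979 (the discrimination is trivially
   easy by design) and rewarded with probability `p_ext` conditional on
   correct.

Two modeling decisions deserve emphasis:

- **Readout noise lives on the log-odds scale.**  `σ_m` is additive in
  the choice logit rather than on the evidence sample.  This is the only
  placement for which unbounded noise drives the marginal choice
  probability to exactly one half for every offer (evidence-scale noise
  saturates through the bounded accuracy readout and leaves a bias);
  it also yields the clean dissociation used throughout: increasing
  `σ_m` degrades type II A_ROC while leaving type I A_ROC untouched in
  expectation.
- **The shared-evidence channel is one concrete mechanism, not a
  claim.**  Trial-level metacognitive sensitivity could arise from any
  stimulus feature sampled once and reused at both stages; re-using the
  evidence draw is the simplest such mechanism and produces the two
  phenomena the analyses look for (accuracy of chosen-internal trials
  above the follow-up baseline; the challenge benefit below).

The cTBS manipulation is modeled abstractly as `σ_m × factor` (default
factor 3) in the `alpfc` condition; the `vertex` control multiplies by
exactly 1 and, because every trial consumes a fixed number of random
draws, is byte-identical to the unstimulated condition at equal seeds.

### Default parameters

| parameter | default | meaning / why |
|---|---|---|
| α (threshold) | 0.15 | coherence at ~63% of the accuracy range; places the follow-up curve span ~0.5 → ~0.99 across the ladder |
| β (slope) | 1.3 | moderate psychometric steepness |
| λ (lapse) | 0.02 | small ceiling shortfall |
| γ_int, γ_ext | 0.7 | mild inverse-S distortion, same for both probability types |
| β_choice | 6.0 | log-odds per unit weighted-probability difference |
| σ_e | 0.08 | evidence noise in coherence units |
| σ_m | 1.5 | log-odds readout noise |

These were calibrated once, as a set, so the default observer lands in a
realistic regime for this task family: follow-up accuracy rising from
chance to near ceiling across the coherence ladder, type II A_ROC ≈
0.69–0.72, type I A_ROC ≈ 0.93, internal/external reward rates within a
few points of each other, and a positive challenge benefit.  They are
study conditions, not tuning knobs, and the tests run against them.

## Analyses

**Optimality and type II A_ROC.**  Trials at the four intermediate
coherences {.03, .06, .12, .25} are labeled internal-optimal when the
expected internal reward — follow-up accuracy × the internal option's
certain payout — is at least `p_ext` (ties favor internal: the internal
payout carries no additional risk).  Hit rate (choosing internal when
internal-optimal) and false-alarm rate (choosing internal when
external-optimal) are computed per coherence; the four points plus
anchors (0,0) and (1,1), sorted by FA rate, are integrated
trapezoidally.  An all-one-class sample raises an explicit error rather
than silently returning 0.5; coherence levels missing one class are
dropped with a warning.

**Type I A_ROC and M-ratio.**  Left-response hit and false-alarm rates
on internal perceptual trials give `A = Φ((Z(hit) − Z(fa))/√2)` and
`d′ = Z(hit) − Z(fa)`.  Rates of exactly 0 or 1 are pulled interior with
a `(k + 0.5)/(n + 1)` correction.  Zero-coherence trials are excluded by
default (their correct direction is objectively ambiguous; configurable).
Sensitivities are read off the areas with the standard identities
`d′ = √2·Z(A_I)` and `meta-d′ = √2·Z(A_II)`, so
`M-ratio = Z(A_II)/Z(A_I)` and equals 1 whenever the two areas agree —
the sanity anchor the implementation is checked against.

**Lagged logistic models.**  The coherence ladder is linearized by rank
(index 0–7 rescaled to [0,1]; a log transform is available — the two are
equivalent after z-scoring only for an exactly geometric ladder).  Lag
terms index *encounters*: the k-th previous trial on which that task
type was actually chosen, never crossing session boundaries.  Rows with
incomplete histories are dropped and counted (zero-imputing after
z-scoring would silently mean "average history").  All predictors are
z-scored within session after row selection.  Fitting is in-package
IRLS with step-halving (monotone log-likelihood), convergence at
coefficient change < 1e−8, explicit perfect-separation detection
(naming the diverging columns), and rank-deficiency errors for constant
columns; it agrees with a reference ML logistic solver to 1e−6 on
shared fixtures.  Multi-session data are fitted with one pooled fit
over per-session-normalized designs — the per-participant pattern —
because per-session fits (≈190 rows, 21 parameters) carry enough
small-sample ML bias to distort coefficient recovery.

**Probability weighting.**  Empirical choice curves pair, per option
level, the optimal-choice proportion `p` with the observed-choice
proportion `w`.  `fit_gamma` minimizes unweighted SSE over
γ ∈ [0.05, 20]; because narrow `p` placements can make the SSE
landscape multimodal, a log-spaced grid scan precedes the bounded local
refinement (tolerance 1e−6).  Note the one-parameter form loses
monotonicity in `p` for γ below ≈ 0.28; fits below that value should be
treated as "extreme distortion" rather than a curve estimate.

Recovery of γ is a two-part story, and the distinction matters.  The
*descriptive* recovery study — refitting choice proportions binomially
sampled from `w(p; γ)` itself at the bin sizes and `p` placements a
simulated study produces — recovers γ ∈ {0.4, 0.7, 1.0, 1.5} with mean
absolute error well under 0.05.  The *structural* sweep — fitting the
descriptive curve to full simulated behavior of observers whose
generative γ varies — recovers only a monotone, attenuated mapping:
a hard-threshold value comparison cancels any monotone weighting
entirely, so γ reaches the choice curve only through the soft part of
the comparison, and evidence noise adds an inverse-S attenuation of its
own.  Both studies are reported by the `recover` harness.

**Challenge vs inevitable.**  A trial is a *challenge* when `p_ext`
exceeds the follow-up-implied internal reward probability (the observer
who takes the internal option is declining the better average bet) and
*inevitable* when it falls below; exact ties are excluded.  The
performance contrast restricts to chosen-internal trials at the
moderate coherences {.06, .12}, computes challenge and inevitable
accuracy *within* each coherence, and averages across coherences with
equal weight.  Pooling across coherences instead (available as an
option) confounds the selection benefit with stimulus difficulty,
because low-coherence trials are challenge-classified more often; the
per-coherence form matches comparing the two per-coherence performance
lines directly.  Under the default observer the long-run benefit is
about +0.02 (+0.005 under σ_m × 3), so Monte-Carlo studies of it need
hundreds of pooled sessions; the stimulation contrast additionally uses
common random numbers (same seed in both conditions) to cancel shared
sampling noise from the deltas.

**ROI beta timecourses.**  The synthetic generator places events with
Poisson SOAs (mean 3 s, clipped to 2.5–8.5 s); each event adds a
gamma-variate response `A·(t/t_p)^k · exp(k(1 − t/t_p))` scaled by its
regressor value, with a per-condition time-to-peak so an
accumulation-speed difference can be planted at matched peak height.
Signals are z-scored (hence invariant to constant offsets), oversampled
×20 by linear interpolation, and epoched 0–11 s post onset; at each
epoch time an OLS with intercept regresses the signal across trials on
the z-scored regressor, separately for chosen-internal and
unchosen-internal events (mutually exclusive trial subsets).  The slope
statistic takes β_min as the minimum over the strictly open window
(0, 4) s and β_max as the maximum over (t_min, 11) s, ties to the
earliest time; `slope = (β_max − β_min)/(t_max − t_min)` and
`magnitude = β_max − β_min`.  Sessions are the unit of averaging for
the chosen-vs-unchosen contrast.

## What the synthetic data do and do not establish

The generator reproduces the statistical structure the analyses assume:
a chance-anchored psychometric curve, distorted subjective
probabilities, shared trial-level evidence between stages, probabilistic
reward, balanced offer schedules, and a noise-selective metacognitive
impairment.  It does not emulate sequential dependencies in real
behavior (fatigue, learning, win-stay biases — the lagged model's
history terms are genuinely null under the generator), reaction times,
eye movements, or any hemodynamic realism beyond a smooth unimodal
impulse response.  Passing tests therefore validate the *estimators and
their implementations* — that each statistic recovers planted structure
and sits at its chance anchor when structure is absent — not any claim
about real observers.

## Numerical and degenerate-input conventions

- Trial logs are UTF-8 TSV, booleans 0/1, floats at ≤6 significant
  digits; identical logs serialize to identical bytes.
- RNG streams are keyed `(seed, session_index, trial_index)` with a
  fixed number of draws per trial, so conditions differing only in the
  noise factor stay stream-aligned and the vertex condition is exactly
  the baseline.
- ROC area with fewer than two points, one-class optimality samples,
  single-direction perceptual samples, areas outside (0,1) for M-ratio,
  constant-DV designs, and empty challenge/inevitable cells all raise
  explicit errors naming the offending quantity; nothing degrades to a
  silent 0.5 or 0.
- Session lengths not divisible by 64 fill the last block from one more
  shuffled grid pass (a warning is raised except at the canonical 195).

## Known limitations

- The external-option perceptual accuracy is a fixed constant (0.979),
  not itself a psychometric process.
- The ±90° stimulus rotation between stages is modeled only as
  statistical independence of the response axis, not geometrically.
- Group-level inference (t-tests, ANOVAs across participants) is out of
  scope; the package computes per-participant statistics and leaves
  cohort inference to the caller.
- The challenge benefit's small long-run size under the default
  observer means single-study estimates of it are noisy; treat
  session-level values as draws, not effects.
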