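# metaprob

Simulation and analysis of **prospective metacognitive choice**: how a
decision maker weighs an *internal* probability — the chance that they
will perform a perceptual task correctly — against an *external*
probability — the chance that a correct performance will actually be
rewarded.

The package targets a two-stage task built on random-dot kinematograms
(RDKs).  On every trial the observer first sees two options: an internal
option whose motion coherence *c* (one of 0, .03, .06, .12, .25, .37,
.50, .75) sets how hard the upcoming left/right discrimination will be,
and an external option whose dot count advertises a reward probability
*p* (one of .1, .3, .5, .6, .7, .8, .9, 1.0).  The observer picks one
option (the metacognitive judgment), then performs the discrimination on
it; a correct response pays off with certainty for the internal option
and with probability *p* for the external one.  Choosing well requires a
*prospective* estimate of one's own success probability, before
attempting the task.

`metaprob` provides, runnable end to end on synthetic data with no
downloads:

- **`agent_sim`** — a parameterized generative observer: a Weibull
  psychometric curve over coherence, trial-level evidence
  `e ~ N(c, σ_e)` shared between the metacognitive and perceptual
  stages, Prospect-Theory probability distortion `w(p; γ)`, a softmax
  choice with log-odds readout noise `σ_m`, and an abstract cTBS
  (theta-burst stimulation) manipulation that inflates `σ_m`.
- **`sdt_metrics`** — the signal-detection indices: **type II A_ROC**
  (how well option choices track which option was optimal, from
  per-coherence hit/false-alarm rates with trapezoidal integration),
  **type I A_ROC** = Φ((Z(hit) − Z(FA))/√2) for perceptual
  discrimination, and metacognitive efficiency
  **M-ratio = meta-d′/d′ = Z(A_II)/Z(A_I)**.
- **`choice_models`** — the trial-history logistic regression
  ln(y/(1−y)) = α + β_int·x_int + β_ext·x_ext + Σ_{k=1..3} (outcome,
  probability, and outcome×probability terms of the k-th previous
  encounter of each task type), fitted by an in-package IRLS solver, and
  the single-predictor decision-variable model.
- **`utility_fit`** — the one-parameter weighting function
  w(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ}, empirical choice curves
  (objective vs subjective probability per option level), and bounded
  least-squares recovery of γ.
- **`challenge_analysis`** — "challenge" trials (the rejected external
  offer was, on average, the better bet) versus "inevitable" trials, and
  the accuracy benefit that trial-level metacognition confers on
  challenge trials at moderate coherences (.06, .12).
- **`roi_slope`** — beta-timecourse machinery for region-of-interest
  signals: per-timepoint regression of an epoched signal on chosen- and
  unchosen-internal-probability regressors, 20× oversampling, and the
  slope statistic (β_max − β_min)/(t_max − t_min) with β_min taken on
  0 < t < 4 s and β_max on t_min < t < 11 s.
- **`task_core` / `pipeline` / `cli`** — trial-log TSV I/O, the
  end-to-end harness, and a `metaprob` command-line tool.

## Worked example

```python
from metaprob.agent_sim import SimulationSpec, simulate_study
from metaprob.pipeline import pooled_followup
from metaprob.sdt_metrics import sdt_summary
from metaprob.challenge_analysis import classify_challenge, challenge_contrast

spec = SimulationSpec(n_sessions=4)           # 4 x 195 trials, default observer
sessions = simulate_study(spec, seed=1)
trials = [t for main, _ in sessions for t in main.trials]
followup = pooled_followup([f for _, f in sessions])

res = sdt_summary(trials, followup)
print(f"type II A_ROC = {res.type_two.area:.3f}")
print(f"type I  A_ROC = {res.type_one.area:.3f}")
print(f"M-ratio       = {res.m_ratio:.3f}")

con = challenge_contrast(trials, classify_challenge(trials, followup))
print(f"challenge - inevitable accuracy = {con.difference:+.3f}")
```

prints

```
type II A_ROC = 0.756
type I  A_ROC = 0.925
M-ratio       = 0.482
challenge - inevitable accuracy = +0.110
```

The observer's option choices track which option was optimal well above
chance (type II A_ROC ≈ 0.76 on this small sample), its perceptual
discrimination is strong (type I ≈ 0.93), metacognitive efficiency is
partial (M-ratio ≈ 0.5 — choices carry less information than the
perceptual evidence itself), and perceptual accuracy on moderately hard
internal trials is higher when the observer deliberately rejected a
better external offer (the challenge benefit — the signature of genuine
trial-level prospective metacognition; its long-run size under the
default observer is about +0.02, so a 4-session sample like this one
carries substantial Monte-Carlo noise).

The same analyses run from the shell:

```bash
metaprob simulate --out run/ --seed 1
metaprob analyze sdt --trials run/session_00.tsv --trials run/session_01.tsv \
    --followup run/followup_table.tsv --out run/sdt.json
metaprob pipeline --out run2/ --seed 1       # every stage, one command
```

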