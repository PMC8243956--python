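# Methods

## Model

A single-layer discriminative learner maps a 65-unit input (for a 60-verb
lexicon: 60 one-hot lexical units, one 0/1 causative unit, four continuous
semantic units in [0, 1]) to three softmax output units, one per construction:
less-transparent causative, more-transparent causative, other (noncausative).
There are no hidden layers, no minibatching, no regularization, and — by
default — no bias unit; weights start at zero, so the untrained model assigns
1/3 to every construction. Interrogation encodes a verb with its semantic
profile and the causative unit set to 1, with learning off, and reads the
three activations as graded acceptability.

### Update rule

The delta-rule step is `w_k += η (t_k − a_k) x`. Two readings of "a_k" are
supported behind `LearnerConfig.loss`:

* `xent` (default): `a` is the softmax output, i.e. the cross-entropy
  gradient. Its fixed point is the maximum-likelihood multinomial-logit fit,
  which is the equivalence the model's regression interpretation rests on;
  that equivalence is verified directly in the test suite (max per-input KL
  against an independently fitted MLE below 1e-3, in practice ~1e-6).
* `lms`: classic Widrow–Hoff least mean squares on the linear outputs, kept
  for sensitivity checks (interrogation still applies the softmax).

Learning rate defaults to 0.01, constant within a run. The MLE-equivalence
check instead uses many shuffled passes with a 1/t-decaying rate, the standard
Robbins–Monro schedule for converging a stochastic approximation to its fixed
point. Softmax logits are max-shifted before exponentiation. The per-exemplar
loop exploits input sparsity (≤ 6 active units) and is numba-jitted; a dense
reference implementation (`learner.update`) is held equal to the jitted kernel
by tests.

## Training distribution

Per-language verb-by-construction count tables are pooled into a composite by
drawing `n_per_language` (default 300,000) exemplars per language,
multinomially over each language's cell proportions. Sampling is with
replacement throughout — it keeps any sample size valid regardless of corpus
size, and exemplar streams (default 10,000 per epoch) are drawn the same way.
Restricting a stream to the training fold excludes held-out verbs' cells
before sampling, so a held-out verb can never appear in training; this is
audited in the tests.

Each epoch draws a fresh 10,000-exemplar stream by default
(`resample_per_epoch=True`), matching the stochastic-presentation framing of
online discriminative learning; the alternative reading — one fixed
10,000-exemplar set per run, reshuffled every epoch — is available with
`resample_per_epoch=False`.

## Semantics

Per-rater ratings (any declared instrument bounds; default 1–9, a required
configuration rather than an assumption) are pooled as the mean over all
raters of all languages, then rescaled affinely to [0, 1]. The
random-semantics control permutes whole 4-feature profiles across verb
identities — never individual features, so every per-feature moment and the
4×4 feature correlation matrix over verbs are exactly preserved — and the
permutation is fixed within a run. A fresh permutation is drawn per run by
default (`permutation_per_run=True`), so across-run dispersion under the
control reflects permutation variability.

## Evaluation

48 runs × 50 epochs by default. Per run, a fresh random split-half partition
(30 train / 30 held out of 60), or one random held-out fold of k = 4 (15
verbs). After each epoch every verb is interrogated; three measures are
correlated with across-participant human means: the difference score
`a_less − a_more` against mean(less) − mean(more), and the raw less/more
activations against the corresponding mean ratings.

Correlations are computed per run and then aggregated (mean, SD with ddof 1,
count) over runs — the headline series, since across-run error bars require a
per-run distribution. A run-averaged variant (activations averaged over the
runs in which each verb was seen/unseen, then one correlation per epoch) is
emitted alongside. Undefined correlations (constant vector on either side)
are recorded as missing and excluded from aggregation, never coerced to 0.

Significance gates use one-tailed critical values
`r_crit = t_crit / sqrt(t_crit² + df)`: df = 58 for full-lexicon comparisons,
28 for split-half sets (n = 30), 43/13 for four-fold train/held-out sets.

## Seed lineage

One master seed derives every substream as
`master·10⁶ + run·10³ + epoch (mod 2³¹)`; run slot 999 is the fold plan,
epoch slot 999 the per-run permutation, and the pipeline reserves
(999, 998)/(999, 997) for composite pooling and preset generation. Identical
configuration and seed reproduce every output byte for byte, and the pipeline
manifest embeds the config snapshot so `dircause run --config manifest.json`
re-executes a completed run exactly.

## Synthetic data generator

The generator emulates the assumed data-generating structure, not any real
corpus. A latent directness-of-causation value θ per verb is evenly spaced on
[0, 1] with seeded jitter. From θ:

* **Semantic ratings** — monotone maps (event_merge = θ, requires = θ²,
  autonomy = 1 − θ, directive = (1 − θ)²) scaled to the instrument range plus
  Gaussian rater noise (SD as a fraction of the range, default 0.10),
  truncated to bounds; 5 languages × 20 raters.
* **Corpus counts** — per-verb token totals from a lognormal (long-tailed)
  distribution; a token is noncausative with probability `other_rate` (0.5 —
  roughly half of a verb's corpus occurrences are noncausative uses), else
  less-transparent with probability σ(β(θ − ½) + δ_lang), with β the effect
  strength (default 6, giving form preferences that saturate near the ends of
  the continuum) and δ_lang ~ N(0, 0.25) a small per-language intercept making
  the five languages non-identical.
* **Judgments** — 48 participants; unit-scale acceptability
  accept_less = σ(β(θ − ½)) and
  accept_more = (1 − λ)·σ(−β(θ − ½)) + λ·0.97, each plus Gaussian participant
  noise (default 0.10), discretized as clip(round(1 + 4·accept), 1..5). The
  leniency parameter λ ∈ [0, 1] interpolates the more-transparent curve toward
  a flat ceiling rather than adding a logit offset: an additive offset would
  preserve the θ trend and so could not emulate across-the-board tolerance for
  the periphrastic form, whose empirical signature is a more-form correlation
  hovering near zero. At λ = 0 the two formulations coincide.

Presets: `strong` (defaults above), `null` (β = 0, severing the latent from
both corpus and judgments), `balinese-like` (λ = 1).

What the generator does **not** emulate: real lexical frequency profiles,
cross-feature rater disagreement structure, participant-level response styles,
or any distributional match to the deposited human datasets. Passing tests
therefore demonstrate that the pipeline recovers structure the generator puts
in — internal validity — not that the effect holds in any natural language.
Against the strong preset the recovered correlations are far higher (~0.99)
than those reported for real data (~0.5–0.75), as expected when the
generating latent is exactly one-dimensional and noise is modest.

## Problem sizes and numerical choices

Full-scale study conditions (48 × 50 × 10,000, composite of 1.5 M exemplars)
are used in the acceptance checks; unit tests and examples use scaled-down
protocols (≤ 8 runs, ≤ 15 epochs) chosen as the smallest sizes at which the
qualitative pattern is stable. Tolerances: activation normalization to 1e-12;
kernel-vs-reference weight agreement to 1e-10; MLE equivalence below 1e-3 KL;
law-of-large-numbers sampling checks at n = 1e5 within ±0.01 (goodness-of-fit
not rejected at α = 0.001). Ties in Likert discretization are impossible by
construction (round of a continuous variable); clipping handles the scale
ends.

## Known limitations

* The headline per-run-then-aggregate correlation and the run-averaged
  variant can diverge early in training when individual runs are unstable;
  both are always reported.
* With zero initialization and no bias, the model cannot express base-rate
  preferences before the first exemplar arrives; the first interrogation
  therefore always starts from indifference.
* Because OTHER exemplars always carry causative = 0, the causative unit's
  weights grow slowly without bound under `xent`; activations remain
  well-behaved (softmax is shift-invariant) but raw weights are not
  interpretable as bounded association strengths.
* The generator's single-latent design means the four semantic features are
  mutually redundant by construction; it cannot probe which feature carries
  the generalization.
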