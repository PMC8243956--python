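# dircause

Discriminative learning of causative construction choice from cross-linguistic
corpus frequencies and event semantics.

## The problem

Many languages offer two dedicated causative constructions: a compact,
**less-transparent** form (English *Somebody broke the window*; a transitive
or morphological causative) and a **more-transparent** periphrastic form built
around an overt causative verb (*Somebody MADE the window break*).
Typological work holds that the choice between them is governed universally by
the **directness of causation**: spatio-temporally merged causer/causee events
favor the compact form, autonomous caused events the periphrastic one.

`dircause` implements a computational test of that claim for researchers in
computational psycholinguistics: a discriminative learner is trained on pooled
verb-by-construction frequencies from several languages, with each verb's
semantics supplied as continuous ratings, and is then asked to predict human
acceptability judgments — including for verbs it has never seen in training,
and in a language it was never trained on.

## The model

A single-layer (perceptron-style) network in the Widrow–Hoff / Rescorla–Wagner
tradition. For a 60-verb lexicon the input is a 65-vector

* 60 one-hot lexical units (verb identity),
* 1 causative unit (1 if the utterance conveys causation),
* 4 semantic units in [0, 1]: **Event-Merge**, **Autonomy**, **Directive**,
  **Requires** — mean rater judgments of the caused event,

fully connected to three softmax outputs, one per construction
(less-transparent / more-transparent / other). Training is online by the
delta rule: for output unit *k*,

```
w_k  <-  w_k + η (t_k − a_k) x
```

with one-hot target *t*, softmax activations *a*, and learning rate η = 0.01.
Under random presentation order the learner converges to the
maximum-likelihood multinomial-logit fit to its training distribution. After
each epoch of 10,000 exemplars the model is interrogated with learning
switched off (causative unit set to 1); the activation difference
`a_less − a_more` per verb is correlated (Pearson) with participants' mean
5-point judgment difference, separately for seen and held-out verbs.

The evaluation protocol comprises 48 runs × 50 epochs with split-half (or
four-fold) validation, a **random-semantics control** (whole 4-feature
profiles permuted across verbs, isolating pure lexical learning), and
one-tailed critical values `r = t / sqrt(t² + df)` for significance gating.

Because the human datasets are not redistributed here, the package ships a
first-class synthetic generator (`dircause.synth`): a latent directness value
per verb drives corpus preferences, semantic features, and judgments, so the
whole pipeline is testable end-to-end and parameter recovery is measurable.

## Worked example

`examples/04_random_semantics_control.py` trains a scaled-down protocol
(8 runs × 15 epochs) on the strong-signal synthetic preset, with and without
the permutation control:

```
intact semantics  : diff r seen = +0.997, unseen = +0.999 (critical 0.31)
permuted semantics: diff r seen = +0.997, unseen = +0.011 (critical 0.31)
```

With intact semantics the model predicts difference-score judgments both for
trained verbs and for verbs it never saw — generalization carried entirely by
the four semantic features. Permuting semantic profiles across verbs leaves
seen-verb prediction intact (the model can still learn each verb's corpus
statistics lexically) but unseen-verb correlation collapses to chance, well
below the one-tailed p < .05 critical value of 0.31 (df = 28). The other
examples generate a dataset, trace single-verb learning trajectories, and run
split-half validation.

The same pipeline is scriptable from the shell:

```bash
dircause synth --preset strong --seed 1 --out fixtures/
dircause corpus pool --counts 'fixtures/counts_*.csv' --n-per-language 300000 --seed 1 --out composite.csv
dircause semantics pool --ratings fixtures/ratings.csv --scale 1 9 --verbs composite.csv --out profiles.csv
dircause train --composite composite.csv --profiles profiles.csv --runs 48 --epochs 50 --seed 1 --out runs/
dircause evaluate --runs runs/ --judgments fixtures/judgments.csv --out results/ --plot
dircause run --config config.yaml        # everything above from one YAML file
```

Real rating, count, and judgment tables in the documented CSV schemas (see
`docs/methods.md`) drop into the same commands in place of the synthetic
fixtures.

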