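"""Train one model run and watch two verbs' acceptability develop.

After each epoch of 10,000 exemplars the learner is interrogated with the
causative unit on; the three softmax activations are its graded acceptability
for the less-transparent, more-transparent, and other forms.
"""

import numpy as np

from dircause.corpus import build_composite_corpus, sample_exemplars
from dircause.learner import LearnerConfig, init_learner, interrogate, train_epoch
from dircause.synth import generate_dataset, preset_config

ds = generate_dataset(preset_config("strong", seed=1))
composite = build_composite_corpus(ds.corpora, 300_000, seed=2)
profiles = ds.pooled_profiles()

state = init_learner(LearnerConfig(learning_rate=0.01), len(ds.lexicon))
direct = int(np.argmax(ds.theta))  # prefers the compact (less-transparent) causative
indirect = int(np.argmin(ds.theta))  # prefers the periphrastic (more-transparent) one

print("epoch   direct verb: a_less a_more | indirect verb: a_less a_more")
for epoch in range(1, 11):
    stream = sample_exemplars(composite, 10_000, seed=epoch)
    train_epoch(state, stream, profiles, 0.01)
    a_d = interrogate(state, direct, profiles.profile(direct))
    a_i = interrogate(state, indirect, profiles.profile(indirect))
    print(
        f"{epoch:>5}   {a_d[0]:.2f}  {a_d[1]:.2f}          |"
        f"       {a_i[0]:.2f}  {a_i[1]:.2f}"
    )
# The direct-causation verb's less-transparent activation rises while the
# indirect verb develops the opposite preference — the difference score
# (a_less - a_more) separates the two within a few epochs.
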