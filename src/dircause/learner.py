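"""Single-layer discriminative learner of construction choice.

The model is a perceptron-style learner in the Rescorla-Wagner / Widrow-Hoff
tradition: no hidden layers, a 65-unit input (for a 60-verb lexicon: 60 one-hot
lexical units, one 0/1 causative unit, four continuous semantic units in
[0, 1]) fully connected to three softmax output units, one per construction
(less-transparent, more-transparent, other).  Weights start at zero, so the
untrained model is indifferent (1/3 each), and are updated online by the delta
rule.  Under random presentation order the learner converges toward the
maximum-likelihood multinomial-logit fit to its training distribution.

Interrogation presents a verb's lexical and semantic units with the causative
unit set to 1, learning switched off; the three output activations are read as
graded acceptability of the three forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .corpus import Construction, ExemplarStream
from .errors import ValidationError
from .semantics import N_FEATURES, ProfileMap, SemanticProfile

#: extra (non-lexical) input units: causative flag + four semantic features
N_EXTRA = 1 + N_FEATURES
N_OUTPUTS = 3


@dataclass(frozen=True)
class LearnerConfig:
    learning_rate: float = 0.01
    use_bias: bool = False
    loss: str = "xent"  # {"xent", "lms"}
    init: str = "zeros"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.loss not in ("xent", "lms"):
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.init != "zeros":
            raise ValidationError(f"unknown init {self.init!r}")


@dataclass
class LearnerState:
    weights: np.ndarray  # (3, n_verbs + 5)
    bias: Optional[np.ndarray]  # (3,) or None
    config: LearnerConfig = field(default_factory=LearnerConfig)
    step_count: int = 0

    @property
    def n_verbs(self) -> int:
        return self.weights.shape[1] - N_EXTRA


def init_learner(config: LearnerConfig, n_verbs: int) -> LearnerState:
    """Zero-initialized state: 3 x (n_verbs + 5) weights, optional zero bias."""
    if n_verbs < 1:
        raise ValidationError("n_verbs must be >= 1")
    weights = np.zeros((N_OUTPUTS, n_verbs + N_EXTRA))
    bias = np.zeros(N_OUTPUTS) if config.use_bias else None
    return LearnerState(weights=weights, bias=bias, config=config, step_count=0)


def encode_exemplar(
    verb_id: int, causative: int, profile: SemanticProfile, n_verbs: int
) -> np.ndarray:
    """One-hot lexical slot + causative flag + the four semantic activations."""
    if not 0 <= verb_id < n_verbs:
        raise ValidationError(f"verb_id {verb_id} out of range [0, {n_verbs})")
    if causative not in (0, 1):
        raise ValidationError("causative flag must be 0 or 1")
    x = np.zeros(n_verbs + N_EXTRA)
    x[verb_id] = 1.0
    x[n_verbs] = float(causative)
    x[n_verbs + 1 :] = profile
    return x


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def activations(state: LearnerState, x: np.ndarray) -> np.ndarray:
    """Softmax of weights @ x (+ bias); positive, sums to 1."""
    z = state.weights @ x
    if state.bias is not None:
        z = z + state.bias
    if not np.isfinite(z).all():
        raise FloatingPointError("non-finite logits")
    return _softmax(z)


def update(
    state: LearnerState, x: np.ndarray, target: Construction | int, learning_rate: float
) -> LearnerState:
    """One delta-rule step, in place; also returns the state for chaining.

    xent: w_k += lr * (t_k - softmax_k(Wx)) * x   (cross-entropy gradient)
    lms:  w_k += lr * (t_k - (Wx)_k) * x          (Widrow-Hoff least mean squares)
    """
    if learning_rate <= 0:
        raise ValidationError("learning_rate must be positive")
    t = np.zeros(N_OUTPUTS)
    t[int(target)] = 1.0
    if state.config.loss == "xent":
        err = t - activations(state, x)
    else:
        z = state.weights @ x
        if state.bias is not None:
            z = z + state.bias
        err = t - z
    state.weights += learning_rate * np.outer(err, x)
    if state.bias is not None:
        state.bias += learning_rate * err
    state.step_count += 1
    return state


def train_epoch(
    state: LearnerState,
    stream: ExemplarStream,
    profiles: ProfileMap,
    learning_rate: float,
) -> LearnerState:
    """Apply one update per exemplar, in stream order (jitted inner loop)."""
    if len(stream) == 0:
        raise ValidationError("training stream is empty")
    if learning_rate <= 0:
        raise ValidationError("learning_rate must be positive")
    if stream.verb_ids.max(initial=-1) >= len(profiles):
        raise ValidationError("stream contains a verb with no semantic profile")
    sem = profiles.values[stream.verb_ids]
    bias = state.bias if state.bias is not None else np.zeros(N_OUTPUTS)
    kernel = (
        _kernels.train_stream_xent
        if state.config.loss == "xent"
        else _kernels.train_stream_lms
    )
    kernel(
        state.weights,
        bias,
        state.bias is not None,
        stream.verb_ids.astype(np.int64),
        stream.causative.astype(np.int64),
        np.ascontiguousarray(sem, dtype=np.float64),
        stream.labels.astype(np.int64),
        float(learning_rate),
    )
    state.step_count += len(stream)
    return state


def interrogate(state: LearnerState, verb_id: int, profile: SemanticProfile) -> np.ndarray:
    """Acceptability probe: verb + semantics with the causative unit on, no learning."""
    x = encode_exemplar(verb_id, 1, profile, state.n_verbs)
    return activations(state, x)


def interrogate_all(state: LearnerState, profiles: ProfileMap) -> np.ndarray:
    """Vectorized interrogation of every verb; returns (n_verbs, 3)."""
    n = state.n_verbs
    if len(profiles) != n:
        raise ValidationError("profiles do not match the learner's lexicon size")
    W = state.weights
    z = W[:, :n].T + W[:, n] + profiles.values @ W[:, n + 1 :].T
    if state.bias is not None:
        z = z + state.bias
    if not np.isfinite(z).all():
        raise FloatingPointError("non-finite logits")
    return _softmax(z)
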