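import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dircause.corpus import CompositeCorpus, Construction, sample_exemplars
from dircause.errors import ValidationError
from dircause.learner import (
    LearnerConfig,
    activations,
    encode_exemplar,
    init_learner,
    interrogate,
    interrogate_all,
    train_epoch,
    update,
)
from dircause.semantics import ProfileMap, SemanticProfile

ZERO_PROFILE = SemanticProfile(0.0, 0.0, 0.0, 0.0)


class TestInitAndEncode:
    def test_weight_shapes(self):
        assert init_learner(LearnerConfig(), 60).weights.shape == (3, 65)
        assert init_learner(LearnerConfig(), 1).weights.shape == (3, 6)
        with pytest.raises(ValidationError):
            init_learner(LearnerConfig(), 0)

    def test_untrained_state_is_indifferent(self, profiles5):
        state = init_learner(LearnerConfig(), 5)
        x = encode_exemplar(2, 1, profiles5.profile(2), 5)
        np.testing.assert_allclose(activations(state, x), [1 / 3] * 3)
        np.testing.assert_allclose(interrogate_all(state, profiles5), 1 / 3)

    def test_encoding_layout(self):
        x = encode_exemplar(0, 1, ZERO_PROFILE, 60)
        assert x[0] == 1 and x[60] == 1 and x.sum() == 2
        y = encode_exemplar(59, 0, SemanticProfile(1, 1, 1, 1), 60)
        assert y[59] == 1 and y[60] == 0 and y[61:].tolist() == [1, 1, 1, 1]
        assert y[:60].sum() == 1  # one-hot lexical slice
        with pytest.raises(ValidationError):
            encode_exemplar(60, 1, ZERO_PROFILE, 60)


class TestActivations:
    def test_softmax_closed_form(self):
        state = init_learner(LearnerConfig(), 1)
        state.weights[0, 0] = np.log(2.0)  # logits (ln 2, 0, 0)
        x = encode_exemplar(0, 0, ZERO_PROFILE, 1)
        np.testing.assert_allclose(activations(state, x), [0.5, 0.25, 0.25])

    @given(st.floats(-50, 50))
    def test_shift_invariance(self, c):
        state = init_learner(LearnerConfig(), 2)
        state.weights[:, 0] = [1.3, -0.2, 0.5]
        x = encode_exemplar(0, 0, ZERO_PROFILE, 2)
        base = activations(state, x)
        state.weights[:, 0] += c  # adds c to every logit
        np.testing.assert_allclose(activations(state, x), base, atol=1e-12)

    @given(st.integers(0, 4), st.floats(0, 1), st.floats(0, 1))
    def test_outputs_normalized(self, verb, em, au):
        rng = np.random.default_rng(0)
        state = init_learner(LearnerConfig(), 5)
        state.weights[:] = rng.normal(0, 2, state.weights.shape)
        a = activations(state, encode_exemplar(verb, 1, SemanticProfile(em, au, 0.5, 0.5), 5))
        assert abs(a.sum() - 1.0) < 1e-12
        assert (a > 0).all()


class TestUpdate:
    def test_gradient_vanishes_at_saturation(self):
        state = init_learner(LearnerConfig(), 1)
        state.weights[0, 0] = 80.0  # a -> (1, 0, 0) to machine precision
        x = encode_exemplar(0, 0, ZERO_PROFILE, 1)
        before = state.weights.copy()
        update(state, x, Construction.LESS_TRANSPARENT, 0.1)
        assert np.abs(state.weights - before).max() < 1e-8

    def test_lms_zero_error_is_exact_fixed_point(self):
        state = init_learner(LearnerConfig(loss="lms"), 1)
        state.weights[:, 0] = [1.0, 0.0, 0.0]  # y == target exactly
        x = np.zeros(6)
        x[0] = 1.0
        before = state.weights.copy()
        update(state, x, Construction.LESS_TRANSPARENT, 0.5)
        np.testing.assert_array_equal(state.weights, before)

    def test_inactive_input_columns_untouched(self, profiles5):
        state = init_learner(LearnerConfig(), 5)
        x = encode_exemplar(2, 1, profiles5.profile(2), 5)
        update(state, x, Construction.MORE_TRANSPARENT, 0.1)
        inactive_lexical = [0, 1, 3, 4]
        assert (state.weights[:, inactive_lexical] == 0).all()
        assert state.step_count == 1

    def test_repeated_updates_converge_monotonically(self):
        state = init_learner(LearnerConfig(), 1)
        x = encode_exemplar(0, 1, SemanticProfile(0.3, 0.7, 0.2, 0.9), 1)
        history = []
        for _ in range(200):
            update(state, x, Construction.OTHER, 0.2)
            history.append(activations(state, x)[int(Construction.OTHER)])
        diffs = np.diff(history)
        assert (diffs > -1e-12).all()
        assert history[-1] > 0.99

    def test_learning_rate_contract(self):
        state = init_learner(LearnerConfig(), 1)
        x = encode_exemplar(0, 0, ZERO_PROFILE, 1)
        with pytest.raises(ValidationError):
            update(state, x, Construction.OTHER, 0.0)


class TestTrainEpoch:
    def _stream(self, n, seed=0):
        comp = CompositeCorpus(
            counts=np.array([[5, 1, 4], [1, 6, 3], [2, 2, 2], [9, 1, 5], [3, 3, 3]]),
            provenance=(),
        )
        return sample_exemplars(comp, n, seed=seed)

    def test_matches_sequential_reference_updates(self, profiles5):
        stream = self._stream(400, seed=8)
        fast = init_learner(LearnerConfig(), 5)
        train_epoch(fast, stream, profiles5, 0.05)
        slow = init_learner(LearnerConfig(), 5)
        for ex in stream:
            x = encode_exemplar(ex.verb_id, ex.causative, profiles5.profile(ex.verb_id), 5)
            update(slow, x, ex.label, 0.05)
        np.testing.assert_allclose(fast.weights, slow.weights, atol=1e-10)
        assert fast.step_count == slow.step_count == 400

    def test_lms_kernel_matches_reference(self, profiles5):
        stream = self._stream(200, seed=9)
        fast = init_learner(LearnerConfig(loss="lms"), 5)
        train_epoch(fast, stream, profiles5, 0.02)
        slow = init_learner(LearnerConfig(loss="lms"), 5)
        for ex in stream:
            x = encode_exemplar(ex.verb_id, ex.causative, profiles5.profile(ex.verb_id), 5)
            update(slow, x, ex.label, 0.02)
        np.testing.assert_allclose(fast.weights, slow.weights, atol=1e-10)

    def test_step_count_and_contracts(self, profiles5):
        stream = self._stream(1000)
        state = init_learner(LearnerConfig(), 5)
        train_epoch(state, stream, profiles5, 0.01)
        assert state.step_count == 1000
        from dircause.corpus import ExemplarStream

        empty = ExemplarStream(
            verb_ids=np.empty(0, np.int32), labels=np.empty(0, np.int8)
        )
        with pytest.raises(ValidationError):
            train_epoch(state, empty, profiles5, 0.01)
        with pytest.raises(ValidationError):
            train_epoch(state, stream, profiles5, 0.0)


class TestInterrogation:
    def test_interrogation_is_pure(self, profiles5):
        state = init_learner(LearnerConfig(), 5)
        stream = TestTrainEpoch()._stream(500, seed=2)
        train_epoch(state, stream, profiles5, 0.05)
        w = state.weights.copy()
        a1 = interrogate(state, 3, profiles5.profile(3))
        a2 = interrogate(state, 3, profiles5.profile(3))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(state.weights, w)

    def test_single_class_limit(self, profiles5):
        # a verb observed only as LESS-transparent causative drives a_less -> 1
        comp = CompositeCorpus(counts=np.array([[50, 0, 0]]), provenance=())
        profiles = ProfileMap(values=profiles5.values[:1])
        state = init_learner(LearnerConfig(), 1)
        for seed in range(40):
            train_epoch(state, sample_exemplars(comp, 50, seed=seed), profiles, 0.1)
        a = interrogate(state, 0, profiles.profile(0))
        assert a[int(Construction.LESS_TRANSPARENT)] > 0.95

    def test_interrogate_all_matches_per_verb(self, profiles5):
        state = init_learner(LearnerConfig(), 5)
        train_epoch(state, TestTrainEpoch()._stream(300, seed=5), profiles5, 0.05)
        batch = interrogate_all(state, profiles5)
        for v in range(5):
            np.testing.assert_allclose(batch[v], interrogate(state, v, profiles5.profile(v)))


def test_training_commutes_with_verb_relabeling(profiles5):
    """Permuting verb identities (lexicon order) commutes with training."""
    comp = CompositeCorpus(
        counts=np.array([[5, 1, 4], [1, 6, 3], [2, 2, 2], [9, 1, 5], [3, 3, 3]]),
        provenance=(),
    )
    stream = sample_exemplars(comp, 800, seed=4)
    perm = np.array([3, 0, 4, 1, 2])  # new_id = perm[old_id]
    state = init_learner(LearnerConfig(), 5)
    train_epoch(state, stream, profiles5, 0.05)

    from dircause.corpus import ExemplarStream

    relabeled = ExemplarStream(
        verb_ids=perm[stream.verb_ids].astype(np.int32), labels=stream.labels
    )
    inv = np.argsort(perm)
    relabeled_profiles = ProfileMap(values=profiles5.values[inv])
    state2 = init_learner(LearnerConfig(), 5)
    train_epoch(state2, relabeled, relabeled_profiles, 0.05)

    a = interrogate_all(state, profiles5)
    b = interrogate_all(state2, relabeled_profiles)
    np.testing.assert_allclose(a, b[perm], atol=1e-12)
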