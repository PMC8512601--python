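"""Ensemble combination: sub-windows, averaging oracle, reduction laws."""

import numpy as np
import pytest

from conftest import ConstantLearner, StubLearner
from dte.ensemble import (
    DeepTimeEnsemble,
    EnsembleResults,
    StandardEnsemble,
    subwindows,
    train_dte,
)
from dte.learners import LearnerConfig, fit
from dte.windowing import WindowSizeSet, extract_all


class TestSubwindows:
    def test_halving_gives_two(self):
        outer = np.arange(20).reshape(20, 1)
        subs = subwindows(outer, 10, 10)
        assert subs.shape == (2, 10, 1)
        np.testing.assert_array_equal(subs[0][:, 0], np.arange(10))
        np.testing.assert_array_equal(subs[1][:, 0], np.arange(10, 20))

    def test_identity_subwindow(self):
        outer = np.random.default_rng(0).normal(size=(15, 2))
        subs = subwindows(outer, 15, 15)
        assert subs.shape == (1, 15, 2)
        np.testing.assert_array_equal(subs[0], outer)

    def test_three_nonoverlapping_with_trailing_drop(self):
        outer = np.arange(100).reshape(100, 1)
        subs = subwindows(outer, 30, 30)
        assert subs.shape[0] == 3
        assert [s[0, 0] for s in subs] == [0, 30, 60]  # [0,30),[30,60),[60,90)

    def test_too_long_subwindow_rejected(self):
        with pytest.raises(ValueError):
            subwindows(np.zeros((5, 1)), 6, 1)


def _ensemble(members, stride=None):
    return EnsembleResults(
        members, sampling_rate=1.0, inner_stride_rule=stride,
        distinct_sizes=len({m[1].window_samples for m in members})
        == len(members),
    )


def _brute_force_combined(outer, members, stride):
    """Literal nested-loop evaluation of the sub-window averaging scheme."""
    w1 = outer.shape[0]
    member_outputs = []
    for _, learner in members:
        wj = learner.window_samples
        if wj == w1:
            member_outputs.append(learner.predict_proba(outer)[0])
        else:
            step = wj if stride is None else stride
            rows = []
            j = 0
            while j + wj <= w1:  # slide until the sequence ends
                rows.append(learner.predict_proba(outer[j : j + wj])[0])
                j += step
            member_outputs.append(np.mean(rows, axis=0))
    return np.mean(member_outputs, axis=0)


class TestPredictSequence:
    def test_average_of_constant_members(self):
        members = [
            (2.0, ConstantLearner([1.0, 0.0], window_samples=10)),
            (1.0, ConstantLearner([0.0, 1.0], window_samples=5)),
        ]
        ens = _ensemble(members)
        probs = ens.predict_sequence(np.zeros((10, 1)))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_member_subwindow_average(self):
        # member whose 3 sub-window outputs are (1,0),(0,1),(0,1)
        class ByStart:
            window_samples = 10
            n_channels = 1
            n_classes = 2

            def predict_proba(self, x):
                x = np.atleast_3d(x)
                out = []
                for w in (x if x.ndim == 3 else [x]):
                    out.append([1.0, 0.0] if w[0, 0] == 0 else [0.0, 1.0])
                return np.array(out)

        # outer window of 30 samples; first sample of sub-window k is 10k
        outer = np.arange(30, dtype=float).reshape(30, 1)
        shell = _ensemble(
            [(30.0, ConstantLearner([0.5, 0.5], 30)), (10.0, ByStart())]
        )
        probs = shell.predict_matrix(outer[None]).per_member_probabilities
        np.testing.assert_allclose(probs[1][0], [1 / 3, 2 / 3])

    def test_exhaustive_stub_oracle_small_grid(self):
        # every (w1, wj, stride) on a small grid agrees with the explicit
        # nested-loop evaluation
        rng = np.random.default_rng(7)
        for w1 in (4, 9, 14):
            outer = rng.normal(size=(w1, 2))
            for wj in range(1, w1 + 1):
                for stride in range(1, wj + 1):
                    if wj == w1:
                        members = [(float(w1), StubLearner(w1, 2))]
                    else:
                        members = [
                            (float(w1), StubLearner(w1, 2)),
                            (float(wj), StubLearner(wj, 2, salt=1.0)),
                        ]
                    ens = _ensemble(members, stride=stride)
                    expected = _brute_force_combined(outer, members, stride)
                    np.testing.assert_allclose(
                        ens.predict_sequence(outer), expected, atol=1e-12
                    )

    def test_wrong_outer_length_rejected(self):
        ens = _ensemble([(5.0, StubLearner(5, 1))])
        with pytest.raises(ValueError):
            ens.predict_sequence(np.zeros((6, 1)))


class TestPredictMatrix:
    def test_empty_input(self):
        ens = _ensemble([(5.0, StubLearner(5, 1))])
        result = ens.predict_matrix(np.empty((0, 5, 1)))
        assert result.probabilities.shape == (0, 3)
        assert len(result.predicted_labels) == 0

    def test_duplicated_rows_duplicated_outputs(self):
        ens = _ensemble(
            [(8.0, StubLearner(8, 1)), (3.0, StubLearner(3, 1, salt=2.0))]
        )
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 8, 1))
        doubled = np.concatenate([x, x])
        probs = ens.predict_matrix(doubled).probabilities
        np.testing.assert_allclose(probs[:4], probs[4:], atol=1e-14)

    def test_rows_sum_to_one_and_labels_match_argmax(self):
        ens = _ensemble(
            [(8.0, StubLearner(8, 2)), (5.0, StubLearner(5, 2, salt=0.5))]
        )
        x = np.random.default_rng(3).normal(size=(10, 8, 2))
        result = ens.predict_matrix(x)
        np.testing.assert_allclose(result.probabilities.sum(axis=1), 1.0,
                                   atol=1e-6)
        np.testing.assert_array_equal(
            result.predicted_labels, result.probabilities.argmax(axis=1)
        )

    def test_confidence_softening(self):
        # combined max-probability never exceeds the largest member max
        ens = _ensemble(
            [(8.0, StubLearner(8, 1)), (4.0, StubLearner(4, 1, salt=3.0)),
             (2.0, StubLearner(2, 1, salt=-1.0))]
        )
        x = np.random.default_rng(5).normal(size=(20, 8, 1)) * 3
        result = ens.predict_matrix(x)
        member_max = result.per_member_probabilities.max(axis=2)  # (N, n)
        combined_max = result.probabilities.max(axis=1)
        assert np.all(combined_max <= member_max.max(axis=0) + 1e-12)


@pytest.fixture(scope="module")
def trained_pair(tiny_dataset):
    """A 2-member window-size ensemble plus its training matrices."""
    train, _, _ = tiny_dataset
    config = LearnerConfig(architecture="conv", n_filters=6, kernel_size=5,
                           epochs=4, batch_size=32, learning_rate=0.02)
    window_set = WindowSizeSet((3.0, 2.0))
    fitted = train_dte(
        train, window_set, config, step_rule=("seconds", 1.0), seed=10,
        n_classes=6,
    )
    return fitted, train, config


class TestTraining:
    def test_structure(self, trained_pair):
        fitted, _, _ = trained_pair
        assert fitted.n_members == 2
        assert fitted.window_sizes == [3.0, 2.0]
        assert [m.window_samples for m in fitted.members] == [60, 40]

    def test_single_window_reduces_to_bare_learner(self, tiny_dataset):
        train, _, _ = tiny_dataset
        config = LearnerConfig(architecture="conv", n_filters=6,
                               kernel_size=5, epochs=3, batch_size=32,
                               learning_rate=0.02)
        seed = 21
        fitted = train_dte(
            train, WindowSizeSet((2.0,)), config,
            step_rule=("seconds", 1.0), seed=seed, n_classes=6,
        )
        table = extract_all(train, WindowSizeSet((2.0,)), ("seconds", 1.0))
        import dataclasses

        bare = fit(dataclasses.replace(config, seed=seed), table[2.0],
                   n_classes=6)
        x = table[2.0].values[:50]
        np.testing.assert_array_equal(
            fitted.predict_matrix(x).probabilities, bare.predict_proba(x)
        )

    def test_training_determinism(self, tiny_dataset, trained_pair):
        fitted, train, config = trained_pair
        again = train_dte(
            train, WindowSizeSet((3.0, 2.0)), config,
            step_rule=("seconds", 1.0), seed=10, n_classes=6,
        )
        x = np.random.default_rng(0).normal(size=(5, 60, 2))
        np.testing.assert_array_equal(
            fitted.predict_matrix(x).probabilities,
            again.predict_matrix(x).probabilities,
        )

    def test_zero_window_size_error_names_size(self, tiny_dataset):
        train, _, _ = tiny_dataset
        config = LearnerConfig(epochs=1)
        model = DeepTimeEnsemble(
            train, WindowSizeSet((1000.0, 2.0)), config,
            step_rule=("seconds", 1.0), n_classes=6,
        )
        with pytest.raises(ValueError, match="1000"):
            model.fit(seed=0)

    def test_manifest_round_trip(self, trained_pair, tmp_path):
        fitted, _, _ = trained_pair
        fitted.save(tmp_path / "ens")
        loaded = EnsembleResults.load(tmp_path / "ens")
        x = np.random.default_rng(1).normal(size=(4, 60, 2))
        np.testing.assert_allclose(
            loaded.predict_matrix(x).probabilities,
            fitted.predict_matrix(x).probabilities,
            atol=1e-12,
        )

    def test_summary_lists_members(self, trained_pair):
        fitted, _, _ = trained_pair
        text = fitted.summary()
        assert "members: 2" in text
        assert "conv" in text


class TestStandardEnsemble:
    def test_single_member_reduces_to_bare_learner(self, tiny_dataset):
        train, _, _ = tiny_dataset
        config = LearnerConfig(architecture="conv", n_filters=6,
                               kernel_size=5, epochs=2, batch_size=32)
        std = StandardEnsemble(
            train, 2.0, 1, config, step_rule=("seconds", 1.0), n_classes=6
        ).fit(seed=5)
        table = extract_all(train, WindowSizeSet((2.0,)), ("seconds", 1.0))
        import dataclasses

        bare = fit(dataclasses.replace(config, seed=5), table[2.0], n_classes=6)
        x = table[2.0].values[:30]
        np.testing.assert_array_equal(
            std.predict_matrix(x).probabilities, bare.predict_proba(x)
        )

    def test_members_differ_but_rows_normalize(self, tiny_dataset):
        train, _, _ = tiny_dataset
        config = LearnerConfig(architecture="conv", n_filters=6,
                               kernel_size=5, epochs=2, batch_size=32)
        std = StandardEnsemble(
            train, 2.0, 3, config, step_rule=("seconds", 1.0), n_classes=6
        ).fit(seed=5)
        x = np.random.default_rng(2).normal(size=(6, 40, 2))
        result = std.predict_matrix(x)
        member = result.per_member_probabilities
        assert not np.allclose(member[0], member[1])
        np.testing.assert_allclose(result.probabilities.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_invalid_member_count(self, tiny_dataset):
        train, _, _ = tiny_dataset
        with pytest.raises(ValueError):
            StandardEnsemble(train, 2.0, 0, LearnerConfig())
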