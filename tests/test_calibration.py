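"""ECE, binning, reliability data and temperature scaling."""

import numpy as np
import pytest

from dte.calibration import (
    LOG_EPS,
    apply_temperature,
    bin_index,
    bin_stats,
    binwise_ece,
    ece,
    fit_temperature,
    reliability_data,
    temperature_for_ensemble,
)


def brute_force_ece(probs, labels, n_bins=10):
    """Unvectorized per-example reference implementation."""
    assignments = {}
    for i, row in enumerate(probs):
        conf = max(row)
        best = min(k for k, p in enumerate(row) if p == conf)
        m = 1
        while conf > m / n_bins + 1e-15:
            m += 1
        assignments.setdefault(m, []).append((conf, int(best == labels[i])))
    total = len(probs)
    value = 0.0
    for members in assignments.values():
        confs = [c for c, _ in members]
        hits = [h for _, h in members]
        gap = abs(sum(hits) / len(hits) - sum(confs) / len(confs))
        value += len(members) / total * gap
    return value


def _random_predictions(rng, n=200, k=6):
    probs = rng.dirichlet(np.ones(k) * 0.5, size=n)
    labels = rng.integers(0, k, size=n)
    return probs, labels


# fixture from the hand-worked example: four predictions with
# (confidence, correct) = (0.55, yes), (0.65, no), (0.95, yes), (0.95, yes)
FOUR = np.array(
    [
        [0.55, 0.45],
        [0.35, 0.65],
        [0.95, 0.05],
        [0.95, 0.05],
    ]
)
FOUR_LABELS = np.array([0, 0, 0, 0])


class TestBinIndex:
    @pytest.mark.parametrize(
        "conf,m,expected",
        [(1.0, 10, 10), (0.05, 10, 1), (0.10, 10, 1), (0.0, 10, 1),
         (0.1000001, 10, 2), (0.95, 10, 10), (0.7, 10, 7), (0.65, 10, 7),
         (0.55, 10, 6), (0.5, 4, 2)],
    )
    def test_right_inclusive_edges(self, conf, m, expected):
        assert bin_index(conf, m) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bin_index(1.2, 10)
        with pytest.raises(ValueError):
            bin_index(-0.1, 10)


class TestBinStats:
    def test_perfect_one_hot(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        stats = bin_stats(probs, [0, 1, 2, 1])
        mask = stats.nonempty
        np.testing.assert_allclose(stats.acc_mean[mask], 1.0)
        np.testing.assert_allclose(stats.conf_mean[mask], 1.0)
        np.testing.assert_allclose(stats.gap[mask], 0.0)

    def test_single_wrong_at_07(self):
        stats = bin_stats(np.array([[0.7, 0.3]]), [1])
        assert stats.counts[6] == 1  # bin 7, 0-based index 6
        assert stats.conf_mean[6] == pytest.approx(0.7)
        assert stats.acc_mean[6] == 0.0
        assert stats.gap[6] == pytest.approx(0.7)

    def test_four_example_bins(self):
        stats = bin_stats(FOUR, FOUR_LABELS)
        nonempty = {i + 1 for i in np.flatnonzero(stats.counts)}
        assert nonempty == {6, 7, 10}
        assert stats.counts[5] == 1 and stats.counts[6] == 1
        assert stats.counts[9] == 2
        assert stats.counts.sum() == stats.n_total == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bin_stats(FOUR, [0, 0])


class TestECE:
    def test_hand_computed_value(self):
        # 0.25*0.45 + 0.25*0.65 + 0.5*0.05 = 0.3
        assert ece(FOUR, FOUR_LABELS) == pytest.approx(0.3, abs=1e-12)

    def test_perfect_predictions_zero(self):
        probs = np.eye(4)[[0, 3, 2, 1, 0]]
        assert ece(probs, [0, 3, 2, 1, 0]) == 0.0

    def test_confident_wrong_is_one(self):
        assert ece(np.array([[1.0, 0.0]]), [1]) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ece(np.empty((0, 3)), [])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            probs, labels = _random_predictions(rng)
            assert ece(probs, labels) == pytest.approx(
                brute_force_ece(probs, labels), abs=1e-12
            )

    def test_permutation_invariance_and_bounds(self):
        rng = np.random.default_rng(7)
        probs, labels = _random_predictions(rng, n=500)
        value = ece(probs, labels)
        assert 0.0 <= value <= 1.0
        order = rng.permutation(len(labels))
        assert ece(probs[order], labels[order]) == pytest.approx(value,
                                                                 abs=1e-12)

    def test_calibrated_by_construction_is_small(self):
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(6), size=20_000)
        labels = (probs.cumsum(axis=1) > rng.random((len(probs), 1))).argmax(1)
        assert ece(probs, labels) < 0.03

    def test_overall_gap_bounded_by_ece(self):
        # |mean confidence - accuracy| <= ECE by the triangle inequality
        rng = np.random.default_rng(9)
        for _ in range(20):
            probs, labels = _random_predictions(rng, n=300)
            stats = bin_stats(probs, labels)
            assert (
                abs(stats.mean_confidence - stats.accuracy)
                <= ece(probs, labels) + 1e-12
            )


class TestBinwise:
    def test_four_example_gaps(self):
        gaps = binwise_ece(FOUR, FOUR_LABELS)
        assert gaps[5] == pytest.approx(0.45, abs=1e-12)
        assert gaps[6] == pytest.approx(0.65, abs=1e-12)
        assert gaps[9] == pytest.approx(0.05, abs=1e-12)

    def test_empty_bins_flagged_nan(self):
        gaps = binwise_ece(FOUR, FOUR_LABELS)
        assert np.isnan(gaps[0])  # bin 1 is empty, not gap 0

    def test_weighted_gaps_recover_ece(self):
        rng = np.random.default_rng(4)
        probs, labels = _random_predictions(rng)
        stats = bin_stats(probs, labels)
        gaps = binwise_ece(probs, labels)
        mask = stats.nonempty
        weighted = np.sum(stats.counts[mask] / stats.n_total * gaps[mask])
        assert weighted == pytest.approx(ece(probs, labels), abs=1e-12)


class TestReliabilityData:
    def test_histogram_conservation_and_consistency(self):
        rng = np.random.default_rng(2)
        probs, labels = _random_predictions(rng, n=400)
        report = reliability_data(probs, labels)
        assert report.bins.counts.sum() == 400
        assert report.ece == pytest.approx(ece(probs, labels), abs=1e-15)
        # overall accuracy is the count-weighted mean of bin accuracies
        mask = report.bins.nonempty
        weighted_acc = np.sum(
            report.bins.counts[mask] * report.bins.acc_mean[mask]
        ) / report.bins.n_total
        assert weighted_acc == pytest.approx(report.bins.accuracy, abs=1e-12)

    def test_json_serializable(self, tmp_path):
        import json

        rng = np.random.default_rng(3)
        probs, labels = _random_predictions(rng, n=50)
        report = reliability_data(probs, labels)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["n_total"] == 50
        assert loaded["ece"] == pytest.approx(report.ece)


def _calibrated_scores(rng, n, k=4, scale=1.0):
    scores = rng.normal(0.0, 1.5, size=(n, k))
    probs = np.exp(scores - scores.max(1, keepdims=True))
    probs /= probs.sum(1, keepdims=True)
    labels = (probs.cumsum(axis=1) > rng.random((n, 1))).argmax(1)
    return scores * scale, labels


class TestApplyTemperature:
    def test_identity_at_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(10, 3))
        from dte.nn import softmax

        np.testing.assert_allclose(
            apply_temperature(scores, 1.0), softmax(scores), atol=1e-12
        )

    def test_closed_form_two_class(self):
        probs = apply_temperature(np.array([[2.0, 0.0]]), 2.0)
        e = np.e
        np.testing.assert_allclose(
            probs, [[e / (e + 1), 1 / (e + 1)]], atol=1e-12
        )

    def test_limit_is_uniform(self):
        probs = apply_temperature(np.array([[5.0, 1.0, -3.0]]), 1e9)
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-8)

    def test_argmax_invariance_and_entropy_monotone(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(100, 5)) * 3

        def entropy(p):
            return -(p * np.log(p + 1e-300)).sum(axis=1)

        prev = None
        for t in (0.5, 1.0, 2.0, 5.0, 20.0):
            probs = apply_temperature(scores, t)
            np.testing.assert_array_equal(
                probs.argmax(axis=1), scores.argmax(axis=1)
            )
            h = entropy(probs)
            if prev is not None:
                assert np.all(h >= prev - 1e-10)
            prev = h

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            apply_temperature(np.zeros((1, 2)), 0.0)


class TestFitTemperature:
    def test_calibrated_scores_recover_unity(self):
        rng = np.random.default_rng(21)
        scores, labels = _calibrated_scores(rng, 20_000)
        model = fit_temperature(scores, labels)
        assert model.temperature == pytest.approx(1.0, abs=0.1)

    def test_scale_recovery(self):
        rng = np.random.default_rng(22)
        scores, labels = _calibrated_scores(rng, 20_000, scale=3.0)
        model = fit_temperature(scores, labels)
        assert model.temperature == pytest.approx(3.0, rel=0.1)

    def test_nll_no_worse_than_unscaled(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=(500, 4)) * 4
        labels = rng.integers(0, 4, size=500)
        from dte.calibration import _nll

        model = fit_temperature(scores, labels)
        assert model.nll <= _nll(scores, labels, 1.0) + 1e-12

    def test_missing_class_warns(self):
        rng = np.random.default_rng(24)
        scores = rng.normal(size=(50, 4))
        labels = rng.integers(0, 3, size=50)  # class 3 absent
        with pytest.warns(UserWarning, match="missing classes"):
            fit_temperature(scores, labels)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            fit_temperature(np.empty((0, 3)), [])


class TestEnsembleTemperature:
    def test_unit_temperature_round_trip(self):
        rng = np.random.default_rng(31)
        probs = rng.dirichlet(np.ones(4), size=50)
        recovered = apply_temperature(np.log(probs + LOG_EPS), 1.0)
        np.testing.assert_allclose(recovered, probs, atol=1e-6)

    def test_higher_temperature_lowers_confidence(self):
        rng = np.random.default_rng(32)
        probs = rng.dirichlet(np.ones(4) * 0.3, size=100)
        scores = np.log(probs + LOG_EPS)
        base = apply_temperature(scores, 1.0).max(axis=1)
        soft = apply_temperature(scores, 3.0).max(axis=1)
        assert np.all(soft <= base + 1e-12)

    def test_overconfident_ensemble_yields_t_above_one(self):
        rng = np.random.default_rng(33)
        # overconfident by construction: sharpen calibrated distributions
        scores, labels = _calibrated_scores(rng, 8_000)
        probs = apply_temperature(scores * 2.5, 1.0)
        model = temperature_for_ensemble(probs, labels)
        assert model.temperature > 1.0
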