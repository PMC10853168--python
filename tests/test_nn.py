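"""Neural-network response model: forward pass, training, thresholding."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hapscore import (
    DataError,
    NNModel,
    predict,
    rank_importance,
    reference_model,
    train,
    youden_threshold,
)
from hapscore.nn import standardize

from .conftest import separable_features


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestStandardize:
    def test_fit_set_becomes_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, (50, 3))
        z, st = standardize(x)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (400, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        z, _ = standardize(x)
        assert np.allclose(z, x, atol=1e-10)

    def test_constant_feature_named_in_error(self):
        x = np.ones((10, 3))
        x[:, 0] = np.arange(10)
        x[:, 2] = np.arange(10)
        with pytest.raises(DataError, match="tmb"):
            standardize(x)

    def test_transform_reuses_fit_parameters(self):
        rng = np.random.default_rng(2)
        x = rng.normal(3, 2, (30, 3))
        _, st = standardize(x)
        new = rng.normal(3, 2, (5, 3))
        assert np.allclose(st.transform(new), (new - st.means) / st.scales)


class TestForwardPass:
    def test_reference_model_at_origin(self):
        # sigma(-0.42557 - 1.76532 * sigma(1.9214)) ~ 0.1228
        score = predict(reference_model(), np.zeros((1, 3)))[0]
        assert score == pytest.approx(0.1228, abs=1e-4)
        hand = _sigmoid(-0.42557 - 1.76532 * _sigmoid(1.9214))
        assert score == pytest.approx(hand, abs=1e-12)

    def test_negative_output_weight_makes_score_decreasing_in_hidden(self):
        m = reference_model()
        assert m.w_out < 0
        # drive the hidden unit low / high via the largest input weight
        x_low = np.array([[0.0, 0.0, -10.0]])
        x_high = np.array([[0.0, 0.0, 10.0]])
        assert predict(m, x_low)[0] > predict(m, x_high)[0]

    def test_saturated_hidden_brackets_all_scores(self):
        m = reference_model()
        rng = np.random.default_rng(3)
        xs = rng.normal(0, 2, (200, 3))
        scores = predict(m, xs)
        lo = predict(m, np.array([[50.0, 50.0, 50.0]]))[0]
        hi = predict(m, np.array([[-50.0, -50.0, -50.0]]))[0]
        assert (scores >= lo - 1e-12).all() and (scores <= hi + 1e-12).all()

    def test_row_order_invariance_and_duplicates(self):
        m = reference_model()
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (20, 3))
        x[5] = x[11]
        s = predict(m, x)
        assert s[5] == s[11]
        perm = rng.permutation(20)
        assert np.allclose(predict(m, x[perm]), s[perm])

    def test_serialization_roundtrip(self):
        m = reference_model()
        m2 = NNModel.from_json(m.to_json())
        x = np.random.default_rng(5).normal(0, 1, (7, 3))
        assert np.allclose(predict(m, x), predict(m2, x))
        assert m2.threshold == 0.436


class TestTraining:
    def test_separable_data_reaches_high_auc(self):
        x, y = separable_features(seed=100)
        m = train(x, y, seed=0)
        auc = roc_auc_score(y, predict(m, x))
        assert auc >= 0.95

    def test_same_seed_identical_weights(self):
        x, y = separable_features(seed=101)
        m1 = train(x, y, seed=9)
        m2 = train(x, y, seed=9)
        assert np.array_equal(m1.w_in, m2.w_in)
        assert (m1.b_hidden, m1.w_out, m1.b_out) == \
            (m2.b_hidden, m2.w_out, m2.b_out)
        assert m1.final_sse == m2.final_sse

    def test_null_labels_bounded_training_auc(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(7000 + seed)
            x = rng.normal(0, 1, (200, 3))
            y = rng.integers(0, 2, 200)
            m = train(x, y, seed=seed)
            aucs.append(roc_auc_score(y, predict(m, x)))
        med = float(np.median(aucs))
        assert 0.45 <= med <= 0.70

    def test_single_class_rejected(self):
        x = np.random.default_rng(8).normal(0, 1, (20, 3))
        with pytest.raises(DataError, match="class"):
            train(x, np.ones(20), seed=0)

    def test_too_few_patients_rejected(self):
        x = np.random.default_rng(9).normal(0, 1, (6, 3))
        with pytest.raises(DataError, match="10"):
            train(x, np.array([0, 1, 0, 1, 0, 1]), seed=0)

    def test_end_to_end_recovery_close_to_bayes(self):
        # response truly logistic in the three factors; the trained net's
        # held-out AUC should approach the generative model's
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(8000 + seed)
            n = 400
            x = rng.normal(0, 1, (n, 3))
            logit = 1.2 * x[:, 0] + 0.8 * x[:, 1] - 0.6 * x[:, 2]
            y = (rng.random(n) < _sigmoid(logit)).astype(int)
            m = train(x[: n // 2], y[: n // 2], seed=seed)
            test_auc = roc_auc_score(y[n // 2:], predict(m, x[n // 2:]))
            bayes_auc = roc_auc_score(y[n // 2:], logit[n // 2:])
            gaps.append(bayes_auc - test_auc)
        assert float(np.median(gaps)) <= 0.1


class TestYouden:
    def test_exhaustive_hand_example(self):
        r = youden_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert r.threshold == 0.6
        assert r.j_max == 1.0

    def test_perfect_separation_returns_lowest_positive_score(self):
        r = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.j_max == 1.0
        assert r.threshold == 0.8

    def test_constant_scores_give_zero_j(self):
        r = youden_threshold([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert r.j_max == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            s = rng.random(n).round(2)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            r = youden_threshold(s, y)
            best_j, best_t = -2.0, None
            for t in sorted(set(s)):
                sens = np.sum((s >= t) & (y == 1)) / np.sum(y == 1)
                spec = np.sum((s < t) & (y == 0)) / np.sum(y == 0)
                j = sens + spec - 1
                if j > best_j + 1e-12:
                    best_j, best_t = j, t
            assert r.j_max == pytest.approx(best_j)
            assert r.threshold == best_t

    def test_j_bounded(self):
        rng = np.random.default_rng(13)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        r = youden_threshold(s, y)
        assert (-1 <= r.youden_j).all() and (r.youden_j <= 1).all()


class TestImportance:
    def test_label_copy_ranks_first_and_null_near_zero(self):
        rng = np.random.default_rng(14)
        n = 500
        y = rng.integers(0, 2, n)
        x = np.column_stack([
            y + rng.normal(0, 0.05, n),   # haps: near-copy of the label
            rng.normal(0, 1, n),          # tmb: pure noise
            rng.normal(0, 1, n),          # diversity: pure noise
        ])
        m = train(x, y, seed=1)
        imp = rank_importance(m, x, y, n_permutations=100, seed=2)
        assert imp.iloc[0]["feature"] == "haps"
        noise_rows = imp[imp["feature"] != "haps"]
        assert (noise_rows["importance"].abs() < 0.05).all()

    def test_same_seed_identical_ranking(self):
        x, y = separable_features(seed=102, n=120)
        m = train(x, y, seed=3)
        i1 = rank_importance(m, x, y, n_permutations=20, seed=5)
        i2 = rank_importance(m, x, y, n_permutations=20, seed=5)
        assert i1.equals(i2)

    def test_invalid_permutation_count(self):
        x, y = separable_features(seed=103, n=50)
        m = train(x, y, seed=4)
        with pytest.raises(DataError):
            rank_importance(m, x, y, n_permutations=0, seed=0)
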