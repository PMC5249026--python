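import numpy as np
import pytest

from snoscout.seqio import SequenceRecord
from snoscout.svm import (
    evaluate,
    grid_search,
    load_model,
    make_negatives,
    metrics_from_confusion,
    predict,
    save_model,
    scale_apply,
    scale_fit,
    similarity_split,
    train,
)

from conftest import random_rna


class TestScaling:
    def test_min_max_map_to_unit_interval(self):
        X = np.array([[0.0], [5.0], [10.0]])
        params = scale_fit(X)
        out = scale_apply(params, X)
        assert out.ravel() == pytest.approx([-1.0, 0.0, 1.0])

    def test_out_of_range_not_clipped(self):
        params = scale_fit(np.array([[0.0], [10.0]]))
        assert scale_apply(params, np.array([[15.0]]))[0, 0] == pytest.approx(2.0)
        assert scale_apply(params, np.array([[-5.0]]))[0, 0] == pytest.approx(-2.0)

    def test_constant_feature_maps_to_zero(self):
        params = scale_fit(np.array([[7.0], [7.0], [7.0]]))
        assert scale_apply(params, np.array([[7.0], [3.0]])).ravel().tolist() == [0.0, 0.0]

    def test_dimension_mismatch_errors(self):
        params = scale_fit(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            scale_apply(params, np.zeros((2, 5)))

    def test_training_data_lands_in_unit_box(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6)) * rng.uniform(0.5, 10, size=6)
        params = scale_fit(X)
        out = scale_apply(params, X)
        assert out.min(axis=0) == pytest.approx(np.full(6, -1.0))
        assert out.max(axis=0) == pytest.approx(np.full(6, 1.0))


def _blobs(n=100, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-3, 0.3, size=(n // 2, 2)),
        rng.normal(3, 0.3, size=(n // 2, 2)),
    ])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


def _xor(n=200, seed=0):
    rng = np.random.default_rng(seed)
    centers = [(-2, -2, 0), (2, 2, 0), (-2, 2, 1), (2, -2, 1)]
    X, y = [], []
    for cx, cy, label in centers:
        X.append(rng.normal((cx, cy), 0.4, size=(n // 4, 2)))
        y.extend([label] * (n // 4))
    return np.vstack(X), np.array(y, int)


class TestGridSearch:
    def test_separable_blobs_reach_perfect_cv(self):
        X, y = _blobs()
        C, gamma, acc = grid_search(X, y, exponents=range(-5, 6), folds=5, seed=0)
        assert acc == 1.0

    def test_rbf_solves_xor(self):
        X, y = _xor()
        _, _, acc = grid_search(X, y, exponents=range(-5, 6), folds=5, seed=0)
        assert acc > 0.9

    def test_result_within_requested_grid(self):
        X, y = _blobs(40, seed=3)
        C, gamma, _ = grid_search(X, y, exponents=range(-2, 3), folds=4, seed=1)
        assert 2.0 ** -2 <= C <= 2.0 ** 2
        assert 2.0 ** -2 <= gamma <= 2.0 ** 2

    def test_single_class_errors(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            grid_search(X, np.zeros(10, int), exponents=range(0, 1), folds=2)

    def test_deterministic_under_seed(self):
        X, y = _xor(80, seed=5)
        a = grid_search(X, y, exponents=range(-3, 4), folds=4, seed=9)
        b = grid_search(X, y, exponents=range(-3, 4), folds=4, seed=9)
        assert a == b


class TestTrainPredict:
    def test_separable_problem_held_out_accuracy(self):
        X, y = _blobs(120, seed=2)
        Xt, yt = _blobs(60, seed=7)
        params = scale_fit(X)
        model = train(scale_apply(params, X), y, C=1.0, gamma=1.0, seed=0,
                      scaling=params)
        labels, p = predict(model, scale_apply(params, Xt))
        assert (labels == yt).mean() >= 0.95
        assert ((p >= 0) & (p <= 1)).all()

    def test_training_set_reproduced(self):
        X, y = _blobs(60, seed=4)
        params = scale_fit(X)
        Xs = scale_apply(params, X)
        model = train(Xs, y, C=8.0, gamma=2.0, seed=0, scaling=params)
        labels, _ = predict(model, Xs)
        assert (labels == y).all()

    def test_nan_features_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            train(X, np.array([0, 1]), C=1.0, gamma=1.0)

    def test_model_round_trip_and_feature_order_guard(self, tmp_path):
        X, y = _blobs(60, seed=8)
        Xp = np.hstack([X] + [X] * 6 + [X[:, :1]])  # 15 columns
        params = scale_fit(Xp)
        model = train(scale_apply(params, Xp), y, C=1.0, gamma=0.5, seed=0,
                      scaling=params, sno_class="CD")
        path = tmp_path / "m.model"
        save_model(model, path)
        back = load_model(path)
        labels_a, p_a = predict(model, scale_apply(params, Xp))
        labels_b, p_b = predict(back, scale_apply(params, Xp))
        assert np.array_equal(labels_a, labels_b)
        assert np.allclose(p_a, p_b)
        # corrupting the stored feature order must be refused
        import pickle
        payload = pickle.loads(path.read_bytes())
        payload["feature_names"] = payload["feature_names"][::-1]
        path.write_bytes(pickle.dumps(payload))
        with pytest.raises(ValueError, match="feature-order"):
            load_model(path)


class TestEvaluate:
    def test_printed_confusion_matrices(self):
        report = metrics_from_confusion(tp=98, fn=34, fp=0, tn=200)
        assert round(report.precision * 100, 1) == 100.0
        assert round(report.recall * 100, 1) == 74.2
        assert round(report.f_score * 100, 1) == 85.2
        report = metrics_from_confusion(tp=60, fn=32, fp=4, tn=196)
        assert round(report.precision * 100, 1) == 93.8
        assert round(report.recall * 100, 1) == 65.2
        assert round(report.f_score * 100, 1) == 76.9

    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 1, 0])
        report = evaluate(y, y, y.astype(float))
        assert report.accuracy == 1.0
        assert report.f_score == 1.0
        assert report.rss == 0.0
        assert report.apr == 1.0 and report.auc == 1.0

    def test_single_class_truth_gives_nan_sentinels(self):
        y = np.ones(4, int)
        report = evaluate(y, y, np.full(4, 0.9))
        assert np.isnan(report.apr) and np.isnan(report.auc)

    def test_rss_is_brier_style_mean(self):
        y = np.array([1, 0])
        p = np.array([0.8, 0.3])
        report = evaluate(y, y, p)
        assert report.rss == pytest.approx((0.04 + 0.09) / 2)


class TestSimilaritySplit:
    def test_identical_sequences_stay_together(self):
        rng = np.random.default_rng(0)
        base = random_rna(rng, 80)
        recs = [SequenceRecord(id=f"r{i}", residues=base) for i in range(4)]
        recs += [SequenceRecord(id=f"u{i}", residues=random_rna(rng, 80))
                 for i in range(4)]
        d1, d2 = similarity_split(recs, seed=0)
        ids1, ids2 = {r.id for r in d1}, {r.id for r in d2}
        dupes = {f"r{i}" for i in range(4)}
        assert dupes <= ids1 or dupes <= ids2
        assert ids1 | ids2 == {r.id for r in recs}
        assert not ids1 & ids2

    def test_two_similar_groups_split_apart(self):
        rng = np.random.default_rng(1)
        a, b = random_rna(rng, 100), random_rna(rng, 100)

        def mutate(seq):
            pos = rng.integers(len(seq), size=3)
            out = list(seq)
            for p in pos:
                out[p] = "ACGU"[rng.integers(4)]
            return "".join(out)

        recs = ([SequenceRecord(id=f"a{i}", residues=mutate(a)) for i in range(5)]
                + [SequenceRecord(id=f"b{i}", residues=mutate(b)) for i in range(5)])
        d1, d2 = similarity_split(recs, seed=0)
        groups1 = {r.id[0] for r in d1}
        groups2 = {r.id[0] for r in d2}
        assert groups1 == {"a"} or groups1 == {"b"}
        assert groups1 != groups2

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            similarity_split([SequenceRecord(id="x", residues="ACGU")])


class TestMakeNegatives:
    def test_shape_and_determinism(self, pwms, config, vienna, small_cd):
        positives = [r for r, _ in small_cd[:8]]
        a = make_negatives(positives, "CD", pwms, config, vienna, seed=3)
        b = make_negatives(positives, "CD", pwms, config, vienna, seed=3)
        assert a.shape[1] == 15
        assert a.shape[0] <= len(positives)
        assert np.array_equal(a, b)

    def test_empty_positives_error(self, pwms, config, vienna):
        with pytest.raises(ValueError):
            make_negatives([], "CD", pwms, config, vienna, seed=0)
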