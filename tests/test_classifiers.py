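import numpy as np
import pytest
from scipy import stats as sstats

from sleepso.bilstm import BiLSTMClassifier, _LSTMLayer
from sleepso.classifiers import (
    FEATURE_NAMES,
    PipelineSpec,
    compute_features,
    crossvalidate,
    dtw_feature_matrix,
    dtw_feature_vector,
    dtw_prototypes,
    feature_matrix,
    learning_curve,
    predict,
    select_features,
    train_classifier,
)
from sleepso.dtw_tsi import dtw_distance
from sleepso.events import EventMorphology
from sleepso.exceptions import ParameterError, ValidationError


def make_morph(d_total=1.0, neg=-60.0, pos=40.0, n_pos_peaks=1):
    return EventMorphology(
        d_total=d_total, d_to_negpeak=0.25 * d_total,
        d_neg_to_pospeak=0.5 * d_total, d_pospeak_to_end=0.25 * d_total,
        n_pos_peaks=n_pos_peaks, neg_peak_uV=neg, pos_peak_uV=pos,
        p2p_amplitude_uV=pos - neg, neg_peak_sample=0,
    )


class TestFeatures:
    def test_registry_has_17_entries(self):
        assert len(FEATURE_NAMES) == 17

    def test_flat_zero_segment_amplitude_features_vanish(self):
        morph = EventMorphology(
            d_total=1.0, d_to_negpeak=0.3, d_neg_to_pospeak=0.4,
            d_pospeak_to_end=0.3, n_pos_peaks=0, neg_peak_uV=0.0,
            pos_peak_uV=0.0, p2p_amplitude_uV=0.0, neg_peak_sample=0,
        )
        vec = compute_features(morph, np.zeros(100))
        by_name = dict(zip(FEATURE_NAMES, vec))
        for name in ("neg_peak_uV", "pos_peak_uV", "p2p_amplitude_uV",
                     "mean_uV", "sd_uV", "skewness", "kurtosis",
                     "neg_halfwave_area", "energy"):
            assert by_name[name] == 0.0

    def test_biphasic_template_consistency(self):
        t = np.arange(1000) / 1000.0
        wave = np.where(
            t < 0.5, -60 * np.sin(np.pi * t / 0.5),
            40 * np.sin(np.pi * (t - 0.5) / 0.5),
        )
        vec = compute_features(make_morph(), wave)
        by_name = dict(zip(FEATURE_NAMES, vec))
        assert by_name["p2p_amplitude_uV"] == pytest.approx(100.0)
        assert by_name["d_total"] == pytest.approx(1.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(50, 200))
            wave = rng.normal(0, 30, size=n)
            morph = make_morph(
                d_total=float(rng.uniform(0.8, 3.0)),
                neg=float(wave.min()), pos=float(wave.max()),
                n_pos_peaks=int(rng.integers(1, 4)),
            )
            vec = compute_features(morph, wave)
            by_name = dict(zip(FEATURE_NAMES, vec))
            fs_eff = n / morph.d_total
            # straightforward independent recomputation
            assert by_name["mean_uV"] == pytest.approx(sum(wave) / n, abs=1e-9)
            assert by_name["sd_uV"] == pytest.approx(
                np.sqrt(sum((w - wave.mean()) ** 2 for w in wave) / n), abs=1e-9
            )
            assert by_name["skewness"] == pytest.approx(
                float(sstats.skew(wave)), abs=1e-9
            )
            assert by_name["neg_halfwave_area"] == pytest.approx(
                sum(-w for w in wave if w < 0) / fs_eff, abs=1e-9
            )
            assert by_name["energy"] == pytest.approx(
                sum(w * w for w in wave) / fs_eff, abs=1e-9
            )
            signs = [1 if w > 0 else (-1 if w < 0 else 0) for w in wave]
            nz = [s for s in signs if s != 0]
            assert by_name["n_zero_crossings"] == sum(
                1 for a, b in zip(nz, nz[1:]) if a != b
            )

    def test_purity(self):
        wave = np.sin(np.linspace(0, 3, 80))
        morph = make_morph()
        np.testing.assert_array_equal(
            compute_features(morph, wave), compute_features(morph, wave)
        )


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(1)
    n = 200
    y = np.array(["SO"] * (n // 2) + ["nonSO"] * (n // 2))
    X = rng.normal(size=(n, 17))
    # feature 4 perfectly separates the classes
    X[:, 4] = np.where(y == "SO", 5.0, -5.0) + 0.1 * rng.normal(size=n)
    return X, y


class TestSelection:
    def test_none_is_identity(self, toy):
        X, y = toy
        sel = select_features(X, y, method="none")
        np.testing.assert_array_equal(sel.transform(X), X)

    @pytest.mark.parametrize("method", ["univariate", "importance", "rfe"])
    def test_separating_feature_selected(self, toy, method):
        X, y = toy
        sel = select_features(X, y, method=method, k=1, seed=0)
        reduced = sel.transform(X)
        np.testing.assert_allclose(reduced[:, 0], X[:, 4])

    def test_pca_variance_monotone_in_k(self, toy):
        X, y = toy
        var = {}
        for k in (8, 16):
            sel = select_features(X, y, method="pca", k=k, seed=0)
            var[k] = sel.named_steps["pca"].explained_variance_ratio_.sum()
        assert var[16] >= var[8]

    def test_k_out_of_range_rejected(self, toy):
        X, y = toy
        with pytest.raises(ParameterError):
            select_features(X, y, method="univariate", k=0)
        with pytest.raises(ParameterError):
            select_features(X, y, method="pca", k=18)


@pytest.fixture(scope="module")
def families():
    rng = np.random.default_rng(2)
    waves = []
    for k in range(40):
        t = np.linspace(0, 1, 60)
        if k < 20:
            waves.append(-np.sin(np.pi * t) + 0.05 * rng.normal(size=60))
        else:
            waves.append(np.sin(2 * np.pi * t) + 0.05 * rng.normal(size=60))
    return waves


class TestDTWPrototypes:
    def test_small_set_returned_whole(self, families):
        protos = dtw_prototypes(families, n_prototypes=40)
        assert len(protos) == 40

    def test_two_families_yield_one_medoid_each(self, families):
        protos = dtw_prototypes(families, n_prototypes=2)
        assert len(protos) == 2
        # each medoid is close to one family and far from the other
        d_fam0 = [dtw_distance(p, families[0]) for p in protos]
        d_fam1 = [dtw_distance(p, families[-1]) for p in protos]
        assert (d_fam0[0] < d_fam1[0]) != (d_fam0[1] < d_fam1[1])

    def test_prototypes_are_training_members(self, families):
        protos = dtw_prototypes(families, n_prototypes=5)
        pool = [tuple(np.round(w, 12)) for w in families]
        for p in protos:
            assert tuple(np.round(p, 12)) in pool

    def test_feature_vector_against_elementwise_calls(self, families):
        protos = dtw_prototypes(families, n_prototypes=3)
        vec = dtw_feature_vector(families[5], protos)
        assert vec.size == 3
        for i, p in enumerate(protos):
            assert vec[i] == pytest.approx(dtw_distance(families[5], p))
        j = next(i for i, p in enumerate(protos)
                 if np.array_equal(p, families[5]) or True)
        # a waveform equal to a prototype scores zero against it
        vec_self = dtw_feature_vector(protos[1], protos)
        assert vec_self[1] == 0.0


def separable_xy(n=120, seed=3):
    rng = np.random.default_rng(seed)
    y = np.array(["SO"] * (n // 2) + ["nonSO"] * (n // 2))
    X = rng.normal(size=(n, 2))
    X[:, 0] += np.where(y == "SO", 4.0, -4.0)
    return X, y


class TestTrainPredict:
    def test_rf_separates_toy_data(self):
        X, y = separable_xy()
        model = train_classifier(X, y, "rf", seed=0)
        labels, scores = predict(model, X)
        assert (labels == y).all()
        assert np.all((scores >= 0) & (scores <= 1))
        assert len(labels) == len(X)

    def test_same_seed_same_predictions(self):
        X, y = separable_xy()
        m1 = train_classifier(X, y, "rf", seed=7)
        m2 = train_classifier(X, y, "rf", seed=7)
        rng = np.random.default_rng(0)
        X_new = rng.normal(size=(50, 2))
        np.testing.assert_array_equal(predict(m1, X_new)[0], predict(m2, X_new)[0])

    def test_single_class_rejected(self):
        X, _ = separable_xy()
        with pytest.raises(ValidationError):
            train_classifier(X, ["SO"] * len(X), "rf")

    @pytest.mark.parametrize("kind", ["logreg", "dtree", "svm", "mlp"])
    def test_all_classical_kinds_fit(self, kind):
        X, y = separable_xy(n=60)
        model = train_classifier(X, y, kind, seed=0)
        labels, scores = predict(model, X)
        assert len(labels) == 60
        assert np.all((scores >= 0) & (scores <= 1))


def two_family_waveforms(n, seed, noise=0.2, min_len=40, max_len=70):
    rng = np.random.default_rng(seed)
    waves, labels = [], []
    for _ in range(n):
        m = int(rng.integers(min_len, max_len))
        t = np.linspace(0, 1, m)
        if rng.random() < 0.5:
            waves.append(-np.sin(np.pi * t) + noise * rng.normal(size=m))
            labels.append("SO")
        else:
            waves.append(np.sin(2 * np.pi * t) + noise * rng.normal(size=m))
            labels.append("nonSO")
    return waves, np.array(labels)


class TestBiLSTM:
    def test_overfits_small_training_set(self):
        from sklearn.metrics import balanced_accuracy_score

        waves, labels = two_family_waveforms(50, seed=4)
        clf = BiLSTMClassifier(hidden_sizes=(8,), n_epochs=200,
                               learning_rate=1e-2, seed=0, patience=200)
        clf.fit(waves, labels)
        acc = balanced_accuracy_score(labels, clf.predict(waves))
        assert acc >= 0.98

    def test_prediction_invariant_to_other_batch_members(self):
        # internal padding must be masked: a short waveform's prediction
        # cannot depend on the longest waveform in its batch
        waves, labels = two_family_waveforms(40, seed=5)
        clf = BiLSTMClassifier(hidden_sizes=(6,), n_epochs=30, seed=1)
        clf.fit(waves, labels)
        short = waves[0]
        long = np.zeros(3 * len(short))
        p_alone = clf.predict_proba([short])[0]
        p_batched = clf.predict_proba([short, long])[0]
        assert p_alone == pytest.approx(p_batched, abs=1e-12)

    def test_training_is_deterministic(self):
        waves, labels = two_family_waveforms(30, seed=6)
        p1 = BiLSTMClassifier(n_epochs=5, seed=3).fit(waves, labels).predict_proba(waves)
        p2 = BiLSTMClassifier(n_epochs=5, seed=3).fit(waves, labels).predict_proba(waves)
        np.testing.assert_array_equal(p1, p2)

    def test_lstm_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        layer = _LSTMLayer(d_in=2, d_hidden=3, rng=rng)
        X = rng.normal(size=(4, 6, 2))
        mask = np.ones((4, 6))
        mask[1, 4:] = 0.0  # one partially masked sequence
        R = rng.normal(size=(4, 6, 3))  # fixed projection

        def loss():
            return float(np.sum(layer.forward(X, mask) * R))

        base = loss()
        _ = layer.forward(X, mask)
        dX, (dW, dU, db) = layer.backward(X, R)
        eps = 1e-6
        for param, grad in [(layer.W, dW), (layer.U, dU), (layer.b, db)]:
            flat = param.reshape(-1)
            gflat = np.asarray(grad).reshape(-1)
            for idx in rng.choice(flat.size, size=5, replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                up = loss()
                flat[idx] = old - eps
                down = loss()
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(gflat[idx], rel=1e-4, abs=1e-7)
        # input gradient too
        for (i, t, d) in [(0, 0, 0), (2, 3, 1), (3, 5, 0)]:
            old = X[i, t, d]
            X[i, t, d] = old + eps
            up = loss()
            X[i, t, d] = old - eps
            down = loss()
            X[i, t, d] = old
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(dX[i, t, d], rel=1e-4, abs=1e-7)


class TestCrossvalidate:
    def test_memorizable_data_scores_one(self):
        X, y = separable_xy(n=60)
        X = np.vstack([X, X])
        y = np.concatenate([y, y])
        mean, sd, scores = crossvalidate(
            X, None, y, PipelineSpec(model_kind="rf"), n_repeats=3, seed=0
        )
        assert mean == pytest.approx(1.0)

    def test_random_labels_score_half(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2000, 5))
        y = np.array(["SO" if v < 0.5 else "nonSO" for v in rng.random(2000)])
        mean, _, _ = crossvalidate(
            X, None, y,
            PipelineSpec(model_kind="dtree", hyper_grid={"max_depth": [3]}),
            n_repeats=5, seed=0,
        )
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_too_few_events_rejected(self):
        X, y = separable_xy(n=8)
        with pytest.raises(ValidationError):
            crossvalidate(X, None, y, PipelineSpec(), n_repeats=2, seed=0)

    def test_dtw1nn_pipeline_runs(self):
        from sleepso.dtw_tsi import TSIConfig

        waves, labels = two_family_waveforms(80, seed=9, noise=0.1)
        mean, _, _ = crossvalidate(
            None, waves, labels,
            PipelineSpec(model_kind="dtw1nn", tsi_config=TSIConfig(seed=0),
                         tsi_budget=60),
            n_repeats=2, seed=0,
        )
        assert mean >= 0.9

    def test_dtw_feature_pipeline_runs(self):
        waves, labels = two_family_waveforms(80, seed=10, noise=0.1)
        mean, _, _ = crossvalidate(
            None, waves, labels,
            PipelineSpec(model_kind="logreg", dtw_features=True,
                         n_prototypes=8),
            n_repeats=2, seed=0,
        )
        assert mean >= 0.9


class TestLearningCurve:
    def test_rows_for_each_size_and_trend(self):
        X, y = separable_xy(n=400, seed=11)
        table = learning_curve(
            X, None, y, PipelineSpec(model_kind="rf"), sizes=[30, 200],
            seed=0, n_repeats=2,
        )
        assert list(table["n_train"]) == [30, 200]
        assert table["mean_balanced_accuracy"].iloc[1] >= (
            table["mean_balanced_accuracy"].iloc[0] - 0.02
        )

    def test_oversized_request_rejected(self):
        X, y = separable_xy(n=50)
        with pytest.raises(ParameterError):
            learning_curve(X, None, y, PipelineSpec(), sizes=[45], seed=0)
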