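import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from enose.analysis import (
    AnalysisError,
    build_smellprints,
    confusion_from_labels,
    confusion_metrics,
    lda_fit,
    lda_predict,
    pca_scores,
    round_half_away,
    split_train_validation,
    two_sample_t,
    wilks_lambda,
)
from enose.device import FeatureSelection
from enose.features import CurveExtrema, FeatureVector, SensorFeatures


def make_fv(areas, slopes=None, relatives=None):
    slopes = slopes if slopes is not None else [0.0] * len(areas)
    relatives = relatives if relatives is not None else [0.0] * len(areas)
    ext = CurveExtrema(1.0, 2.0, 1.0)
    return FeatureVector(
        sensors={
            i + 1: SensorFeatures(a, s, r, ext)
            for i, (a, s, r) in enumerate(zip(areas, slopes, relatives))
        }
    )


class TestSmellprints:
    def test_single_measurement_area_gives_seven_vector(self):
        fv = make_fv(list(range(7)))
        (sp,) = build_smellprints([("healthy", fv)], FeatureSelection.AREA)
        assert sp.values.tolist() == list(range(7))
        assert sp.columns == tuple(f"s{i}:area" for i in range(1, 8))

    def test_all_features_give_sensor_major_21_vector(self):
        fv = make_fv([10] * 7, [20] * 7, [30] * 7)
        (sp,) = build_smellprints([("x", fv)], FeatureSelection.ALL)
        assert len(sp.values) == 21
        # sensor-major: s1 triple first, ordered (area, slope, relative)
        assert sp.values[:3].tolist() == [10, 20, 30]
        assert sp.columns[:3] == ("s1:area", "s1:slope", "s1:relative")

    def test_permuting_inputs_permutes_outputs(self):
        fvs = [("a", make_fv([i] * 7)) for i in range(4)]
        fwd = build_smellprints(fvs)
        rev = build_smellprints(fvs[::-1])
        assert [sp.values[0] for sp in fwd] == [sp.values[0] for sp in rev][::-1]

    def test_inconsistent_sensor_sets_rejected(self):
        fv1 = make_fv([1] * 7)
        fv2 = FeatureVector(sensors={1: fv1.sensors[1]})
        with pytest.raises(AnalysisError):
            build_smellprints([("a", fv1), ("b", fv2)])


class TestPca:
    def test_collinear_data_pc1_explains_everything(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        res = pca_scores(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance[1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_covariance_is_diagonal_eigenvalues(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5)) @ rng.normal(size=(5, 5))
        res = pca_scores(X)
        cov = res.scores.T @ res.scores / (len(X) - 1)
        assert np.allclose(cov, np.diag(res.explained_variance), atol=1e-10)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        res = pca_scores(X)
        assert np.allclose(res.scores @ res.loadings.T + res.mean, X, atol=1e-10)

    def test_matches_sklearn_up_to_sign_convention(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        ours = pca_scores(X)
        ref = sklearn_pca(n_components=6).fit(X)
        assert np.allclose(ours.explained_variance, ref.explained_variance_, atol=1e-10)
        for j in range(6):
            dot = abs(ours.loadings[:, j] @ ref.components_[j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(AnalysisError):
            pca_scores(np.ones((1, 3)))


class TestLda:
    def test_separated_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        Xa = rng.normal([0, 0], 0.3, size=(20, 2))
        Xb = rng.normal([4, 4], 0.3, size=(20, 2))
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = lda_fit(X, y)
        assert np.all(lda_predict(model, X) == y)

    def test_one_dimensional_threshold_closed_form(self):
        # hand-derived: w = (mu_b - mu_a)/s2, threshold = w*(mu_a+mu_b)/2
        #               + log(n_a/n_b)
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        y = np.array(["a", "a", "a", "a", "b", "b"])
        mu_a, mu_b = 1.5, 4.5
        s2 = (np.sum((X[:4, 0] - mu_a) ** 2) + np.sum((X[4:, 0] - mu_b) ** 2)) / 4
        w = (mu_b - mu_a) / s2
        threshold = 0.5 * w * (mu_a + mu_b) + np.log(4 / 2)
        model = lda_fit(X, y)
        assert model.w[0] == pytest.approx(w)
        assert model.threshold == pytest.approx(threshold)

    def test_matches_brute_force_separator_on_toy_sets(self):
        """Where an exhaustive search over directions/offsets certifies the
        10-point set linearly separable, LDA separates it too."""

        def brute_force_separable(X, y01):
            for theta in np.linspace(0, np.pi, 721):
                z = X @ np.array([np.cos(theta), np.sin(theta)])
                order = np.argsort(z)
                zs, ys = z[order], y01[order]
                cuts = (zs[:-1] + zs[1:]) / 2
                for c in cuts:
                    pred = (z > c).astype(int)
                    if np.all(pred == y01) or np.all(pred == 1 - y01):
                        return True
            return False

        toys = [
            (np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5],
                       [3, 3], [4, 3], [3, 4], [4, 4], [3.5, 3.5]], dtype=float),
             np.array([0] * 5 + [1] * 5)),
            (np.array([[0, 0], [0.2, 0.1], [0.1, 0.3], [-0.1, 0.2], [0.3, -0.1],
                       [2, 0], [2.2, 0.1], [2.1, 0.3], [1.9, 0.2], [2.3, -0.1]]),
             np.array([0] * 5 + [1] * 5)),
        ]
        for X, y in toys:
            assert brute_force_separable(X, y)
            model = lda_fit(X, y)
            assert np.all(lda_predict(model, X) == y)

    def test_singular_scatter_gets_ridge(self):
        # p=3 but only 4 points on a 2-D subspace: S_w singular
        X = np.array([[0, 0, 0], [1, 1, 0], [3, 3, 0], [4, 4, 0]], dtype=float)
        y = np.array([0, 0, 1, 1])
        model = lda_fit(X, y)
        assert model.ridge > 0
        assert np.all(np.isfinite(model.w))
        assert np.all(lda_predict(model, X) == y)

    def test_one_class_training_rejected(self):
        with pytest.raises(AnalysisError):
            lda_fit(np.ones((4, 2)), np.zeros(4))

    def test_matches_sklearn_predictions(self):
        sk_lda = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(1.5, 1, (25, 3))])
        y = np.array([0] * 25 + [1] * 25)
        ours = lda_predict(lda_fit(X, y), X)
        ref = sk_lda.LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X)
        assert np.mean(ours == ref) >= 0.98


class TestSplit:
    def test_half_split_of_96_gives_48_48(self):
        train, valid = split_train_validation(96, 0.5, seed=0)
        assert len(train) == 48 and len(valid) == 48

    def test_same_seed_same_split(self):
        assert np.array_equal(
            split_train_validation(50, 0.3, seed=7)[0],
            split_train_validation(50, 0.3, seed=7)[0],
        )

    @given(n=st.integers(2, 200), seed=st.integers(0, 100))
    def test_disjoint_exhaustive(self, n, seed):
        train, valid = split_train_validation(n, 0.5, seed=seed)
        merged = np.sort(np.concatenate([train, valid]))
        assert np.array_equal(merged, np.arange(n))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            split_train_validation(1, 0.5, 0)
        with pytest.raises(AnalysisError):
            split_train_validation(10, 1.0, 0)


class TestConfusionMetrics:
    def test_validation_table_of_the_disease_study(self):
        # 48 validation samples: 21+22 correct, 2 false positive, 3 false negative
        report = confusion_metrics(np.array([[21, 3], [2, 22]]))
        assert round_half_away(report.correct_rate_pct) == 89.6
        assert round_half_away(report.false_negative_pct) == 6.3
        assert report.false_positive_pct == pytest.approx(100 * 2 / 48)

    def test_perfect_and_inverted_classifiers(self):
        assert confusion_metrics(np.array([[5, 0], [0, 5]])).correct_rate_pct == 100.0
        assert confusion_metrics(np.array([[0, 5], [5, 0]])).correct_rate_pct == 0.0

    @given(
        counts=st.tuples(*([st.integers(0, 50)] * 4)).filter(lambda c: sum(c) > 0)
    )
    def test_rates_sum_to_exactly_100(self, counts):
        report = confusion_metrics(np.array(counts).reshape(2, 2))
        total = (
            report.correct_rate_pct + report.false_positive_pct + report.false_negative_pct
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(AnalysisError):
            confusion_metrics(np.array([[1, -1], [0, 1]]))

    def test_confusion_from_labels_convention(self):
        y_true = ["h", "h", "d", "d", "d"]
        y_pred = ["h", "d", "d", "d", "h"]
        c = confusion_from_labels(y_true, y_pred, ("d", "h"))
        # rows predicted, cols actual, order (d, h)
        assert c.tolist() == [[2, 1], [1, 1]]


class TestWilksLambda:
    def test_identical_group_means_give_lambda_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 3))
        res = wilks_lambda([base, base + 0.0])
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_univariate_two_group_equals_t_statistic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(12, 1))
        b = rng.normal(1, 1, size=(15, 1))
        res = wilks_lambda([a, b])
        t = two_sample_t(a.ravel(), b.ravel())
        n = len(a) + len(b)
        assert res.wilks_lambda == pytest.approx(1 / (1 + t.t**2 / (n - 2)))
        assert res.approx_F == pytest.approx(t.t**2)
        assert res.p_value == pytest.approx(t.p, rel=1e-9)

    def test_lambda_decreases_with_mean_offset(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        lams = [
            wilks_lambda([a, b + offset]).wilks_lambda for offset in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(l2 < l1 for l1, l2 in zip(lams, lams[1:]))

    def test_invariant_under_common_affine_transform(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=(12, 4)), rng.normal(1, 1, size=(9, 4))]
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        res1 = wilks_lambda(groups)
        res2 = wilks_lambda([g @ A + b for g in groups])
        assert res2.wilks_lambda == pytest.approx(res1.wilks_lambda, rel=1e-9)

    def test_singular_within_matrix_rejected(self):
        a = np.zeros((3, 5))  # p > within-group dof
        b = np.ones((3, 5))
        with pytest.raises(AnalysisError):
            wilks_lambda([a, b])


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)
        assert not res.significant

    def test_swap_negates_t_keeps_p(self):
        a = [1.0, 2.0, 2.5]
        b = [3.0, 4.0, 5.0]
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1.2, 14)
        res = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_matches_permutation_oracle(self):
        """Pooled-t p-value agrees with a label-permutation p-value within
        Monte-Carlo error for small near-normal samples."""
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.0, 1.0, 6)
        observed = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        n_res = 100_000
        idx = np.argsort(rng.random((n_res, 12)), axis=1)
        perm = pooled[idx]
        pa, pb = perm[:, :6], perm[:, 6:]
        va = pa.var(axis=1, ddof=1)
        vb = pb.var(axis=1, ddof=1)
        sp2 = (5 * va + 5 * vb) / 10
        ts = (pa.mean(axis=1) - pb.mean(axis=1)) / np.sqrt(sp2 * (2 / 6))
        p_perm = np.mean(np.abs(ts) >= abs(observed.t))
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_res)
        assert observed.p == pytest.approx(p_perm, abs=max(5 * mc_sd, 0.01))

    def test_insufficient_data_rejected(self):
        with pytest.raises(AnalysisError):
            two_sample_t([1.0], [2.0, 3.0])


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(89.583, 89.6), (4.1667, 4.2), (6.25, 6.3), (-6.25, -6.3), (1.04, 1.0)],
    )
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected
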