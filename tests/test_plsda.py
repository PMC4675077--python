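"""PLS-DA core: autoscaling, NIPALS, calibration, LOOCV, feature ranking."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import gutfuse as gf
from gutfuse.plsda import _nipals_pls1


def _labels(y_enc):
    return np.where(np.asarray(y_enc) > 0, "IBS", "HLT")


def _random_problem(rng, n=20, p=10):
    X = rng.normal(size=(n, p))
    y = np.ones(n)
    y[: n // 2] = -1.0
    rng.shuffle(y)
    return X, y


class TestAutoscale:
    def test_unit_variance_with_sample_sd(self):
        Xs, params = gf.autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xs[:, 0], [-1.0, 0.0, 1.0])  # sd(ddof=1)=1
        assert Xs.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature_maps_to_zero(self):
        Xs, _ = gf.autoscale(np.full((3, 1), 5.0))
        np.testing.assert_array_equal(Xs, np.zeros((3, 1)))

    def test_stored_params_reproduce_scaled_matrix(self, rng):
        X = rng.normal(size=(8, 4))
        Xs, params = gf.autoscale(X)
        np.testing.assert_allclose(params.apply(X), Xs)


class TestNipals:
    def test_first_weight_is_normalized_xty(self, rng):
        for _ in range(5):
            X, y = _random_problem(rng)
            Xs, _ = gf.autoscale(X)
            yc = y - y.mean()
            W, _, _, _ = _nipals_pls1(Xs, yc, 1)
            w0 = Xs.T @ yc
            w0 /= np.linalg.norm(w0)
            if w0[np.argmax(np.abs(w0))] < 0:
                w0 = -w0
            np.testing.assert_allclose(W[:, 0], w0, atol=1e-9)

    def test_scores_match_reference_pls_up_to_sign(self, rng):
        X, y = _random_problem(rng)
        clf = gf.PLSDAClassifier(n_components=3).fit(X, _labels(y))
        ref = PLSRegression(n_components=3, scale=True).fit(X, y)
        for a in range(3):
            t_ref = ref.x_scores_[:, a]
            sign = np.sign(t_ref @ clf.x_scores_[:, a])
            np.testing.assert_allclose(sign * t_ref, clf.x_scores_[:, a], atol=1e-6)

    def test_fitted_invariants_hold(self, rng):
        X, y = _random_problem(rng, n=30, p=12)
        clf = gf.PLSDAClassifier(n_components=4).fit(X, _labels(y))
        np.testing.assert_allclose(
            np.linalg.norm(clf.x_weights_, axis=0), 1.0, atol=1e-9)
        gram = clf.x_scores_.T @ clf.x_scores_
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-6 * np.diag(gram).max()

    def test_explained_y_variance_nondecreasing_in_components(self, rng):
        X, y = _random_problem(rng, n=25, p=8)
        r2 = []
        for k in range(1, 6):
            clf = gf.PLSDAClassifier(n_components=k).fit(X, _labels(y))
            resid = y - clf.decision_function(X)
            r2.append(1 - resid @ resid / (y @ y))
        assert np.all(np.diff(r2) >= -1e-12)

    def test_single_class_and_oversized_components_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="both classes"):
            gf.PLSDAClassifier(1).fit(X, ["IBS"] * 6)
        with pytest.raises(ValueError, match="n_components"):
            gf.PLSDAClassifier(4).fit(X, ["IBS", "HLT"] * 3)


class TestPrediction:
    def test_perfect_single_predictor(self):
        y = np.array([1.0, -1.0] * 5)
        X = y.reshape(-1, 1)
        with pytest.warns(UserWarning, match="degenerate"):
            clf = gf.PLSDAClassifier(n_components=1).fit(X, _labels(y))
        np.testing.assert_allclose(clf.x_weights_[:, 0], [1.0])
        np.testing.assert_allclose(clf.decision_function(X), y, atol=1e-9)
        assert np.corrcoef(clf.decision_function(X), y)[0, 1] == pytest.approx(1.0)

    def test_feature_order_invariance_via_table(self, strong_cohort, strong_models):
        _, genus, _, _, _ = strong_cohort
        gm, _ = strong_models
        yhat = gf.predict_continuous(gm, genus)
        perm = np.random.default_rng(0).permutation(genus.n_features)
        shuffled = gf.FeatureTable(
            genus.sample_ids, [genus.feature_ids[j] for j in perm],
            "genus", genus.values[:, perm])
        np.testing.assert_allclose(gf.predict_continuous(gm, shuffled), yhat)

    def test_feature_mismatch_names_difference(self, strong_models):
        gm, _ = strong_models
        bad = gf.FeatureTable(["s"], ["not_a_feature"], "genus", [[1.0]])
        with pytest.raises(ValueError, match="not_a_feature"):
            gf.predict_continuous(gm, bad)


class TestCalibration:
    def test_symmetric_classes_give_half_at_zero(self):
        cal = gf.PosteriorCalibration(1.0, 0.5, -1.0, 0.5)
        assert cal.p_ibs(0.0) == pytest.approx(0.5)

    def test_well_separated_class_mean_is_confident(self):
        cal = gf.PosteriorCalibration(3.0, 0.5, -3.0, 0.5)  # 12 sd apart
        assert cal.p_ibs(3.0) > 0.95

    def test_equal_sds_posterior_is_monotone_logistic(self):
        cal = gf.PosteriorCalibration(1.0, 0.7, -1.0, 0.7)
        grid = np.linspace(-4, 4, 101)
        p = cal.p_ibs(grid)
        assert np.all(np.diff(p) > 0)
        # closed form: logit(p) linear in yhat
        logit = np.log(p) - np.log1p(-p)
        slopes = np.diff(logit) / np.diff(grid)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-6)

    def test_posteriors_invariant_to_affine_rescaling(self, rng):
        scores = rng.normal(size=40)
        groups = np.array(["IBS", "HLT"] * 20)
        cal = gf.calibrate_posterior(scores, groups)
        cal2 = gf.calibrate_posterior(3.0 * scores + 7.0, groups)
        np.testing.assert_allclose(cal2.p_ibs(3.0 * scores + 7.0),
                                   cal.p_ibs(scores), atol=1e-9)


class TestLOOCV:
    def test_no_leakage_under_permuted_labels(self, strong_cohort):
        # permuting labels destroys signal; accuracy must hover near chance
        _, _, metab, meta, _ = strong_cohort
        rng = np.random.default_rng(2)
        accs = []
        for _ in range(20):
            perm = rng.permutation(meta.n_samples)
            meta_p = gf.SampleMeta(meta.sample_ids,
                                   [meta.group[j] for j in perm])
            posts = gf.loocv_posteriors(metab, meta_p)
            assigned = gf.posterior_assignments(posts)
            accs.append(np.mean(np.array(assigned) == np.array(meta_p.group)))
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_strong_signal_accuracy(self):
        cfg = gf.CohortConfig(seed=21, driver_fold_change=4.0, noise_sigma=0.3)
        _, metab, meta, _ = gf.generate_cohort(cfg)
        posts = gf.loocv_posteriors(metab, meta)
        acc = np.mean(np.array(gf.posterior_assignments(posts))
                      == np.array(meta.group))
        assert acc >= 0.9

    def test_requires_two_per_group(self):
        t = gf.FeatureTable(["a", "b", "c"], ["f1", "f2"], "metabolite",
                            np.arange(6.0).reshape(3, 2))
        meta = gf.SampleMeta(["a", "b", "c"], ["IBS", "HLT", "HLT"])
        with pytest.raises(ValueError, match=">= 2 samples per group"):
            gf.loocv_posteriors(t, meta)


class TestRankDiscriminators:
    def test_perfect_predictor_selected_with_direction(self):
        rng = np.random.default_rng(8)
        y = np.array([1.0, -1.0] * 10)
        X = np.column_stack([rng.normal(size=20) * 0.01, y])  # feature 1 drives
        clf = gf.PLSDAClassifier(n_components=1).fit(
            X, _labels(y), feature_ids=["noise", "driver"])
        assert gf.rank_discriminators(clf, 1) == [("driver", 1)]

    def test_depressed_driver_gets_negative_direction(self, strong_cohort,
                                                      strong_models):
        _, _, _, _, truth = strong_cohort
        gm, mm = strong_models
        ranked = dict(gf.rank_discriminators(gm, 3) + gf.rank_discriminators(mm, 3))
        for fid, d in zip(truth.driver_feature_ids, truth.driver_direction):
            assert ranked.get(fid) == d

    def test_k_exceeding_feature_count_rejected(self, strong_models):
        _, mm = strong_models
        with pytest.raises(ValueError, match="k must be"):
            gf.rank_discriminators(mm, 20)
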