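"""PLS1 fitting, component selection, classification, accuracy accounting, VIP."""

import numpy as np
import pytest

import phenospec as ps
from phenospec.pls import beta_for_components

# Published accuracy-accounting rows: (totals, correct, per-group %, overall %)
# for group order (BH, AR, AS), both spectral regions, both code schemes,
# full-spectrum and selected-band models, calibration and validation splits.
PUBLISHED_ROWS = [
    ((251, 128, 96), (231, 113, 59), (92.0, 88.3, 61.5), 80.6),
    ((126, 64, 48), (110, 57, 22), (87.3, 89.1, 45.8), 74.1),
    ((251, 128, 96), (229, 113, 57), (91.2, 88.3, 59.4), 79.6),
    ((126, 64, 48), (108, 57, 24), (85.7, 89.1, 50.0), 74.9),
    ((251, 128, 96), (218, 118, 68), (86.9, 92.2, 70.8), 83.3),
    ((126, 64, 48), (105, 58, 27), (83.3, 90.6, 56.3), 76.7),
    ((251, 128, 96), (230, 115, 60), (91.6, 89.8, 62.5), 81.3),
    ((126, 64, 48), (117, 58, 26), (92.9, 90.6, 54.2), 79.2),
    ((251, 85, 113), (251, 81, 97), (100.0, 95.3, 85.8), 93.7),
    ((126, 42, 56), (126, 38, 51), (100.0, 90.5, 91.1), 93.8),
    ((251, 85, 113), (251, 75, 84), (100.0, 88.2, 74.3), 87.5),
    ((126, 42, 56), (126, 33, 47), (100.0, 78.6, 83.9), 87.5),
    ((251, 85, 113), (250, 85, 113), (99.6, 100.0, 100.0), 99.9),
    ((126, 42, 56), (126, 42, 56), (100.0, 100.0, 100.0), 100.0),
    ((251, 85, 113), (250, 85, 112), (99.6, 100.0, 99.1), 99.6),
    ((126, 42, 56), (125, 41, 56), (99.2, 97.6, 100.0), 98.9),
]

GROUPS = ("BH", "AR", "AS")


def table_from_counts(totals, correct):
    """Build predicted/truth label vectors realizing the given counts."""
    pred, truth = [], []
    for g, other, t, c in zip(GROUPS, ("AR", "AS", "BH"), totals, correct):
        truth += [g] * t
        pred += [g] * c + [other] * (t - c)
    return np.asarray(pred, dtype=object), np.asarray(truth, dtype=object)


class TestFitPLS1:
    def test_rank_one_exact_fit(self, rng):
        t = rng.standard_normal(25)
        p = rng.standard_normal(10)
        X = np.outer(t, p)
        y = 2.0 * t + 1.0
        model = ps.fit_pls1(X, y, 1)
        resid = y - ps.predict(model, X)
        assert np.abs(resid).max() < 1e-10

    def test_matches_reference_pls_implementation(self, rng):
        """NIPALS beta agrees with scikit-learn's PLSRegression (scale=False)."""
        from sklearn.cross_decomposition import PLSRegression

        for _ in range(5):
            X = rng.standard_normal((30, 20))
            y = rng.standard_normal(30)
            model = ps.fit_pls1(X, y, 5)
            ref = PLSRegression(n_components=5, scale=False).fit(X, y)
            np.testing.assert_allclose(model.beta, ref.coef_.ravel(), atol=1e-8)

    def test_full_rank_limit_reproduces_least_squares(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        model = ps.fit_pls1(X, y, 8)
        Xc = X - X.mean(0)
        beta_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.beta, beta_ols, atol=1e-8)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            ps.fit_pls1(rng.standard_normal((10, 4)), np.ones(10), 2)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_lv"):
            ps.fit_pls1(rng.standard_normal((10, 4)), rng.standard_normal(10), 5)

    def test_score_columns_orthogonal(self, rng):
        X = rng.standard_normal((30, 12))
        y = X @ rng.standard_normal(12) + 0.1 * rng.standard_normal(30)
        model = ps.fit_pls1(X, y, 6)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_explained_ssy_bounded_by_total(self, rng):
        X = rng.standard_normal((30, 12))
        y = X @ rng.standard_normal(12) + 0.1 * rng.standard_normal(30)
        model = ps.fit_pls1(X, y, 6)
        assert np.all(model.ssy_f >= 0)
        assert model.ssy_f.sum() <= model.ssy_total + 1e-9

    def test_training_residuals_nonincreasing_in_components(self, rng):
        X = rng.standard_normal((40, 15))
        y = X @ rng.standard_normal(15) + 0.2 * rng.standard_normal(40)
        model = ps.fit_pls1(X, y, 8)
        rss = []
        for k in range(1, 9):
            resid = (y - y.mean()) - (X - X.mean(0)) @ beta_for_components(model, k)
            rss.append(resid @ resid)
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        model = ps.fit_pls1(X, y, 3)
        assert abs(ps.predict(model, X.mean(0)[None, :])[0] - y.mean()) < 1e-12

    def test_linearity_mean_of_predictions(self, rng):
        X = rng.standard_normal((20, 6))
        model = ps.fit_pls1(X, rng.standard_normal(20), 3)
        batch = rng.standard_normal((7, 6))
        assert abs(ps.predict(model, batch.mean(0)[None, :])[0] - ps.predict(model, batch).mean()) < 1e-10

    def test_factorization_path_agrees_with_beta_path(self, rng):
        """Predicting through scores/loadings equals the collapsed beta vector."""
        X = rng.standard_normal((25, 10))
        y = rng.standard_normal(25)
        model = ps.fit_pls1(X, y, 4)
        Xc = X - model.x_mean
        # factorization path: t_f built by sequential deflation with W, P
        yhat_fact = np.full(len(y), model.y_mean)
        Xf = Xc.copy()
        for f in range(model.n_lv):
            t = Xf @ model.weights[:, f]
            yhat_fact += model.y_loadings[f] * t
            Xf -= np.outer(t, model.loadings[:, f])
        np.testing.assert_allclose(yhat_fact, ps.predict(model, X), atol=1e-10)


class TestChooseNLV:
    def test_forced_single_component(self, rng):
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5)
        assert ps.choose_n_lv(X, y, max_lv=1, folds=3, seed=0) == 1

    def test_recovers_known_latent_dimensionality(self):
        """Three latent factors plus small noise -> 3 or 4 components chosen."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            T = r.standard_normal((80, 3))
            P = r.standard_normal((3, 30))
            X = T @ P + 0.02 * r.standard_normal((80, 30))
            y = T @ np.asarray([1.0, -2.0, 1.5]) + 0.05 * r.standard_normal(80)
            if ps.choose_n_lv(X, y, max_lv=10, folds=5, seed=seed) in (3, 4):
                hits += 1
        assert hits >= 18

    def test_invariant_to_sample_duplication(self):
        # exact rank-2 data: the RMSEP curve drops to numerical zero at k=2,
        # so the parsimony rule must pick 2 with or without duplicated rows
        r = np.random.default_rng(5)
        T = r.standard_normal((40, 2))
        X = T @ r.standard_normal((2, 12))
        y = T @ np.asarray([1.0, -1.0])
        k1 = ps.choose_n_lv(X, y, max_lv=6, folds=4, seed=2)
        k2 = ps.choose_n_lv(np.vstack([X, X]), np.concatenate([y, y]), max_lv=6, folds=4, seed=2)
        assert k1 == k2 == 2


class TestClassify:
    def test_nearest_code_assignment(self, spri_encoding):
        got = ps.classify(np.asarray([-10.0, 49.0, 95.0]), spri_encoding)
        np.testing.assert_array_equal(got, ["BH", "AR", "AS"])

    def test_exact_midpoint_breaks_toward_lower_code(self):
        enc = ps.encode_groups_spri(("BH", "AS"))
        assert ps.classify(np.asarray([50.0]), enc)[0] == "BH"
        assert ps.classify(np.asarray([25.0]), ps.encode_groups_spri(("BH", "AR", "AS")))[0] == "BH"

    def test_joint_affine_invariance(self, rng, spri_encoding):
        """Classification is unchanged by any increasing affine map applied to
        both the scores and the codes."""
        scores = rng.uniform(-20, 120, 50)
        base = ps.classify(scores, spri_encoding)
        for _ in range(10):
            a = rng.uniform(0.1, 5.0)
            b = rng.uniform(-100, 100)
            mapped = ps.GroupEncoding(
                scheme="SPRI",
                codes={g: a * c + b for g, c in spri_encoding.codes.items()},
                reference_group="BH",
            )
            np.testing.assert_array_equal(ps.classify(a * scores + b, mapped), base)


class TestAccuracyTable:
    @pytest.mark.parametrize("totals,correct,per_group,overall", PUBLISHED_ROWS)
    def test_reproduces_published_accounting(self, totals, correct, per_group, overall):
        pred, truth = table_from_counts(totals, correct)
        table = ps.accuracy_table(pred, truth, GROUPS)
        for g, want in zip(GROUPS, per_group):
            assert table.accuracy_display(g) == want
        assert table.overall_display == overall

    def test_all_correct_is_100(self):
        truth = np.repeat(GROUPS, 5)
        table = ps.accuracy_table(truth, truth, GROUPS)
        assert all(table.accuracy_display(g) == 100.0 for g in GROUPS)
        assert table.overall_display == 100.0

    def test_overall_is_macro_not_pooled(self):
        # 87.3/89.1/45.8 -> macro 74.1; pooled would be 79.4
        pred, truth = table_from_counts((126, 64, 48), (110, 57, 22))
        table = ps.accuracy_table(pred, truth, GROUPS)
        assert table.overall_display == 74.1
        pooled = 100.0 * (110 + 57 + 22) / (126 + 64 + 48)
        assert round(pooled, 1) == 79.4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            ps.accuracy_table(np.asarray(["BH"]), np.asarray(["BH"]), GROUPS)


class TestVIP:
    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(10):
            X = rng.standard_normal((25, 15))
            y = X @ rng.standard_normal(15) + 0.3 * rng.standard_normal(25)
            model = ps.fit_pls1(X, y, rng.integers(1, 8))
            v = ps.vip(model)
            assert abs((v**2).mean() - 1.0) < 1e-10

    def test_single_relevant_band_has_maximal_vip(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 3].copy()
        model = ps.fit_pls1(X, y, 3)
        v = ps.vip(model)
        assert int(np.argmax(v)) == 3

    def test_one_component_vip_proportional_to_weights(self, rng):
        X = rng.standard_normal((20, 8))
        y = X @ rng.standard_normal(8)
        model = ps.fit_pls1(X, y, 1)
        v = ps.vip(model)
        w = np.abs(model.weights[:, 0])
        expected = w / np.sqrt((w**2).mean())
        np.testing.assert_allclose(v, expected, atol=1e-10)


class TestModelResultsFacade:
    def test_noise_free_spectra_classify_perfectly_with_two_components(self, spri_encoding):
        arch = ps.make_archetypes("visnir", effect_size=0.08)
        t = ps.simulate_spectra(arch, (12, 12, 12), ps.NoiseConfig(0, 0, 0, 1, 0, seed=0))
        res = ps.PLSDiscriminant.from_table(t, spri_encoding).fit(n_lv=2)
        assert res.accuracy().overall == 100.0

    def test_summary_reports_scheme_components_and_accuracy(self, cal_val, spri_encoding):
        cal, val = cal_val
        res = ps.PLSDiscriminant.from_table(cal, spri_encoding).fit(n_lv=4)
        text = res.summary(val)
        assert "SPRI" in text and "latent variables: 4" in text
        assert "Validation accuracy" in text and "Overall" in text
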