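"""PCA, PLS-DA, OPLS-DA, cross-validated Q2, permutation test and S-line."""

import numpy as np
import pytest

from olivenmr.chemometrics import (
    encode_classes,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    permutation_test,
    q2_crossval,
    select_ncomp_by_cumvar,
    select_ncomp_by_q2,
    sline,
)


def _two_class_data(n_per=20, p=10, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p))
    X[:n_per, 0] += shift
    y = np.array([1.0] * n_per + [0.0] * n_per)
    return X, y


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 7.0)
        v = np.array([2.0, -1.0, 0.5])
        X = np.outer(u, v)
        model = fit_pca(X, 1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_explained_ratio_matches_eigen_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10000, 2)) * np.sqrt([2.0, 1.0])
        model = fit_pca(X, 2)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        ratio = model.explained_variance_fraction[0] / model.explained_variance_fraction[1]
        assert ratio == pytest.approx(evals[0] / evals[1], rel=1e-9)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        model = fit_pca(X, 6)
        recon = model.scores @ model.loadings.T + model.column_means
        assert np.linalg.norm(X - recon) <= 1e-8 * np.linalg.norm(X)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(3).normal(size=(30, 8))
        model = fit_pca(X, 5)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_k_beyond_rank_rejected(self):
        X = np.outer(np.arange(5.0), np.arange(3.0))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 2)

    def test_cumvar_selection(self):
        model = fit_pca(np.random.default_rng(4).normal(size=(50, 10)), 8)
        model.cumulative_R2X = np.cumsum([0.5, 0.3, 0.15, 0.05, 0, 0, 0, 0])
        model.explained_variance_fraction = np.array([0.5, 0.3, 0.15, 0.05, 0, 0, 0, 0])
        assert select_ncomp_by_cumvar(model, 0.99) == 4
        assert select_ncomp_by_cumvar(model, 1e-9) == 1


class TestEncodeClasses:
    def test_indicator_definition(self):
        resp = encode_classes(["A", "B", "A"])
        np.testing.assert_array_equal(resp.indicator, [[1, 0], [0, 1], [1, 0]])
        np.testing.assert_array_equal(resp.binary_column, [1, 0, 1])

    def test_four_classes_column_sums(self):
        labels = ["a"] * 3 + ["b"] * 4 + ["c"] * 2 + ["d"] * 5
        resp = encode_classes(labels)
        assert resp.indicator.shape == (14, 4)
        np.testing.assert_array_equal(resp.indicator.sum(axis=0), [3, 4, 2, 5])
        assert resp.binary_column is None

    def test_singleton_class_rejected_when_strict(self):
        with pytest.raises(ValueError, match="singleton"):
            encode_classes(["A", "B", "B"], min_class_size=2)


class TestPLSDA:
    def test_response_along_first_latent_direction_one_component(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        y = Xc @ vt[0]  # noise-free response along the leading direction
        model = fit_plsda(X, y[:, None], 1)
        assert model.R2Y >= 0.999

    def test_matches_sklearn_pls_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 8))
        Y = rng.normal(size=(20, 2))
        k = 3
        ours = fit_plsda(X, Y, k)
        ref = PLSRegression(n_components=k, scale=False, tol=1e-12, max_iter=10000).fit(X, Y)
        for a in range(k):
            t_ours, t_ref = ours.x_scores[:, a], ref.x_scores_[:, a]
            sign = np.sign(t_ours @ t_ref)
            np.testing.assert_allclose(t_ours, sign * t_ref, atol=1e-6)
        np.testing.assert_allclose(ours.predict(X), ref.predict(X), atol=1e-6)

    def test_row_permutation_equivariance(self):
        X, y = _two_class_data(seed=7)
        resp = encode_classes(["a" if v else "b" for v in y])
        model = fit_plsda(X, resp, 2)
        perm = np.random.default_rng(0).permutation(len(y))
        resp_p = encode_classes(["a" if v else "b" for v in y[perm]])
        model_p = fit_plsda(X[perm], resp_p, 2)
        np.testing.assert_allclose(model_p.x_scores, model.x_scores[perm], atol=1e-8)

    def test_score_orthogonality_and_variance_bookkeeping(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 10))
        Y = rng.normal(size=(25, 3))
        model = fit_plsda(X, Y, 4)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) <= 1e-8 * np.max(np.abs(gram))
        assert model.r2x_per_component.sum() <= 1 + 1e-9
        assert abs(model.R2X - model.r2x_per_component.sum()) < 1e-9


class TestOPLSDA:
    def test_zero_ortho_reduces_to_pls1(self):
        X, y = _two_class_data(seed=9)
        opls = fit_oplsda(X, y, n_ortho=0)
        pls = fit_plsda(X, y[:, None], 1)
        t_o, t_p = opls.predictive_scores, pls.x_scores[:, 0]
        sign = np.sign(t_o @ t_p)
        np.testing.assert_allclose(t_o, sign * t_p, atol=1e-6)
        np.testing.assert_allclose(
            opls.predict(X), pls.predict(X).ravel(), atol=1e-8
        )

    def test_orthogonal_filter_sharpens_class_correlation(self):
        # planted: class direction v plus a strong y-orthogonal direction u
        rng = np.random.default_rng(10)
        n, p = 60, 12
        v = np.zeros(p); v[0] = 1.0
        u = np.zeros(p); u[1] = 1.0
        y = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
        yc = y - y.mean()
        X = np.outer(yc, v) + np.outer(rng.normal(0, 3, n), u) + rng.normal(0, 0.1, (n, p))
        pls1 = fit_plsda(X, y[:, None], 1)
        corr_pls = abs(np.corrcoef(pls1.x_scores[:, 0], y)[0, 1])
        opls = fit_oplsda(X, y, n_ortho=1)
        corr_opls = abs(np.corrcoef(opls.predictive_scores, y)[0, 1])
        assert corr_opls > corr_pls
        # oracle: explicit projection filter by hand linear algebra
        Xc = X - X.mean(axis=0)
        w = Xc.T @ yc; w /= np.linalg.norm(w)
        t = Xc @ w
        pvec = Xc.T @ t / (t @ t)
        wo = pvec - (w @ pvec) * w; wo /= np.linalg.norm(wo)
        to = Xc @ wo
        po = Xc.T @ to / (to @ to)
        Ef = Xc - np.outer(to, po)
        w2 = Ef.T @ yc; w2 /= np.linalg.norm(w2)
        t_oracle = Ef @ w2
        sign = np.sign(t_oracle @ opls.predictive_scores)
        np.testing.assert_allclose(opls.predictive_scores, sign * t_oracle, atol=1e-8)

    def test_predictive_orthogonal_score_orthogonality(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 15))
        y = np.array([0.0, 1.0] * 20)
        model = fit_oplsda(X, y, n_ortho=3)
        t = model.predictive_scores
        for i in range(model.n_ortho):
            assert abs(t @ model.ortho_scores[:, i]) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(model.ortho_scores[:, i])
        assert model.predictive_variance_fraction + model.ortho_variance_fractions.sum() <= 1 + 1e-9

    def test_excessive_ortho_rejected(self):
        X = np.outer(np.array([0.0, 1.0, 0.0, 1.0]), np.ones(3))
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="n_ortho"):
            fit_oplsda(X + 1e-13, y, n_ortho=2)


class TestQ2:
    def test_noise_free_linear_response(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(35, 6))
        y = X @ rng.normal(size=6)
        # full component count recovers the exact linear map on every fold
        assert q2_crossval(X, y[:, None], n_components=6, folds=7, seed=0) >= 0.99

    def test_pure_noise_response_near_zero(self):
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(40, 10))
            y = rng.normal(size=(40, 1))
            q2s.append(q2_crossval(X, y, n_components=2, folds=7, seed=seed))
        assert np.median(q2s) <= 0.05

    def test_loo_equals_naive_loop_oracle(self):
        X, y = _two_class_data(n_per=8, p=5, seed=13)
        n = len(y)
        q2 = q2_crossval(X, y[:, None], n_components=2, folds=n, seed=3)
        # naive leave-one-out loop, written directly from the definition
        press = 0.0
        for i in range(n):
            train = np.setdiff1d(np.arange(n), [i])
            model = fit_plsda(X[train], y[train, None], 2)
            press += float((y[i] - model.predict(X[i : i + 1])[0, 0]) ** 2)
        tss = float(np.sum((y - y.mean()) ** 2))
        assert q2 == pytest.approx(1 - press / tss, abs=1e-10)

    def test_q2_bounded_by_r2y_on_fixture(self, small_scaled_table):
        X = small_scaled_table.values
        resp = encode_classes(small_scaled_table.metadata["cultivar"].tolist())
        model = fit_plsda(X, resp, 2)
        q2 = q2_crossval(X, resp, n_components=2, folds=7, seed=0)
        assert q2 <= model.R2Y + 0.05

    def test_fold_emptying_class_rejected(self):
        X = np.random.default_rng(14).normal(size=(6, 4))
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="class"):
            # some fold removes the only 0-labelled sample
            q2_crossval(X, y[:, None], n_components=1, folds=6, seed=0)

    def test_auto_order_selection_stops_on_decline(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 8))
        y = X[:, :1] + 0.1 * rng.normal(size=(40, 1))
        k = select_ncomp_by_q2(X, y, max_components=6, seed=1)
        # oracle: first index where the Q2 sequence stops improving
        q2s = [q2_crossval(X, y, n_components=a, seed=1) for a in range(1, 7)]
        expected = 1
        for a in range(1, 6):
            if q2s[a] <= q2s[a - 1]:
                break
            expected = a + 1
        assert k == expected


class TestPermutation:
    def test_floor_p_value_on_separable_design(self):
        X, y = _two_class_data(n_per=15, p=8, shift=6.0, seed=16)
        res = permutation_test(X, y[:, None], n_perm=100, seed=0, n_components=1)
        assert res.empirical_p == pytest.approx(1 / 101)
        assert len(res.permuted_Q2) == 100

    def test_null_labels_not_significant(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 6))
        y = rng.integers(0, 2, 30).astype(float)
        while y.sum() in (0, 30):
            y = rng.integers(0, 2, 30).astype(float)
        res = permutation_test(X, y[:, None], n_perm=99, seed=5, n_components=1)
        assert res.empirical_p >= 0.05

    def test_zero_permutations_rejected(self):
        X, y = _two_class_data(n_per=4, p=3)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(X, y[:, None], n_perm=0)


class TestSLine:
    def test_self_correlation_is_one(self):
        X, y = _two_class_data(seed=18)
        model = fit_oplsda(X, y, n_ortho=1)
        X2 = np.column_stack([X, model.predictive_scores])
        line = sline(model, X2)
        assert line.correlation[-1] == pytest.approx(1.0, abs=1e-10)
        finite = line.correlation[np.isfinite(line.correlation)]
        assert np.all(finite <= 1 + 1e-12) and np.all(finite >= -1 - 1e-12)

    def test_planted_year_effect_recovered_on_saturated_bucket(self, coarse_grid):
        # year effect on the saturated component: the 1.26-labelled bucket
        # must rank among the top 3 by |covariance| with the predictive score
        from olivenmr import default_design, generate_cohort
        from olivenmr.preprocessing import (
            build_bucket_table,
            normalize_total_sum,
            pareto_scale,
        )

        design = default_design(
            plants_per_cultivar=10,
            seed=21,
            ppm_grid=coarse_grid,
            year_effects={
                "coratina": {"saturated": 0.03, "oleic": -0.03},
                "cimadimola": {"saturated": 0.03, "oleic": -0.03},
                "ogliarola": {"saturated": 0.03, "oleic": -0.03},
                "peranzana": {"saturated": 0.03, "oleic": -0.03},
            },
        )
        cohort = generate_cohort(design)
        table = pareto_scale(
            normalize_total_sum(build_bucket_table(cohort.spectra, cohort.metadata))
        )
        y = (cohort.metadata["harvest"] == "H2").to_numpy(dtype=float)
        model = fit_oplsda(table.values, y, n_ortho=1)
        line = sline(model, table.values)
        order = np.argsort(-np.abs(line.covariance))
        top3 = [table.labels[i] for i in order[:3]]
        assert "1.26" in top3

    def test_zero_variance_bucket_reported_missing(self):
        X, y = _two_class_data(seed=19)
        model = fit_oplsda(X, y, n_ortho=0)
        X2 = np.column_stack([X, np.full(len(y), 3.0)])
        line = sline(model, X2)
        assert np.isnan(line.correlation[-1])
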