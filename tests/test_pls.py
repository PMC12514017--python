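"""PLS components, spin nulls, and bootstrap ratios."""

import numpy as np
import pandas as pd
import pytest

import protectomap as pm
from protectomap.pls import _spin_indices
from protectomap.spatial import knn_weight_matrix, morans_i
from protectomap.synthdata import sphere_coords


def as_df(x):
    return pd.DataFrame(x, columns=[f"G{j}" for j in range(x.shape[1])])


class TestFit:
    def test_single_gene_outcome_fully_explained(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=80)
        X = as_df(g[:, None])
        model = pm.pls_fit(X, g, n_components=1)
        assert model.var_explained[0] == pytest.approx(1.0, abs=1e-12)
        r, _ = pm.region_score_correlation(model, g, 1)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_outcome_explains_nothing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        X -= X.mean(axis=0)
        raw = rng.normal(size=40)
        raw -= raw.mean()
        # project out every X column
        q, _ = np.linalg.qr(X)
        y = raw - q @ (q.T @ raw)
        model = pm.pls_fit(as_df(X), y, n_components=1, scale_x=False)
        assert model.var_explained[0] == pytest.approx(0.0, abs=1e-10)

    def test_planted_weights_recovered(self):
        """y = X w* + noise at SNR 4: the first weight vector aligns with w*.

        Recovery of a dense w* by the one-step weight X'y requires more
        observations than predictors (with n < m the sample covariance
        rotates w* away regardless of noise), so the check runs in the
        well-determined regime."""
        rng = np.random.default_rng(2)
        n, m = 499, 50
        X = rng.normal(size=(n, m))
        w_star = rng.normal(size=m)
        w_star /= np.linalg.norm(w_star)
        signal = X @ w_star
        noise = rng.normal(size=n)
        y = signal + noise * signal.std() / (2.0 * noise.std())  # SNR 4 in variance
        model = pm.pls_fit(as_df(X), y, n_components=1, scale_x=False)
        corr = np.corrcoef(model.weights[:, 0], w_star)[0, 1]
        assert corr > 0.9

    def test_constant_outcome_rejected(self):
        X = as_df(np.random.default_rng(3).normal(size=(20, 4)))
        with pytest.raises(ValueError, match="constant"):
            pm.pls_fit(X, np.ones(20))

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(4)
        X = as_df(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="rank"):
            pm.pls_fit(X, rng.normal(size=10), n_components=5)

    def test_variance_fractions_sum_to_ols_r2(self):
        """Summed over all rank components, the per-component y-variance
        fractions equal the least-squares R^2 of y on X (oracle: lstsq)."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        model = pm.pls_fit(as_df(X), y, n_components=4, scale_x=False)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        r2 = 1 - ((yc - Xc @ beta) ** 2).sum() / (yc ** 2).sum()
        assert model.var_explained.sum() == pytest.approx(r2, abs=1e-10)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(6)
        X = as_df(rng.normal(size=(60, 20)))
        model = pm.pls_fit(X, rng.normal(size=60), n_components=3)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.diag(gram).max() < 1e-8

    def test_sign_convention_and_global_flip(self):
        """Flipping y's sign flips weights and scores but leaves explained
        fractions and |bootstrap ratios| unchanged."""
        rng = np.random.default_rng(7)
        X = as_df(rng.normal(size=(50, 10)))
        y = rng.normal(size=50)
        m1 = pm.pls_fit(X, y, n_components=2)
        m2 = pm.pls_fit(X, -y, n_components=2)
        assert np.allclose(m1.var_explained, m2.var_explained)
        assert np.allclose(m1.weights, -m2.weights)
        assert np.allclose(m1.scores, -m2.scores)
        b1 = pm.bootstrap_gene_weights(X, y, (1,), n_boot=50, seed=0)
        b2 = pm.bootstrap_gene_weights(X, -y, (1,), n_boot=50, seed=0)
        assert np.allclose(np.abs(b1.ratio), np.abs(b2.ratio))

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check: scikit-learn's NIPALS PLS regression
        produces the same first-component weights up to sign."""
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=60)
        model = pm.pls_fit(as_df(X), y, n_components=2, scale_x=True)
        ref = PLSRegression(n_components=2, scale=True).fit(X, y)
        for k in range(2):
            w_ref = ref.x_weights_[:, k] / np.linalg.norm(ref.x_weights_[:, k])
            dot = abs(model.weights[:, k] @ w_ref)
            assert dot == pytest.approx(1.0, abs=1e-6)


class TestSpins:
    def test_identity_rotation_gives_identity_permutation(self, geom120):
        xyz = sphere_coords(geom120)
        perm = _spin_indices(xyz, np.eye(3))
        assert np.array_equal(perm, np.arange(len(xyz)))

    def test_same_seed_reproduces_nulls(self, geom120):
        a = pm.spin_permutations(geom120, 50, seed=5)
        b = pm.spin_permutations(geom120, 50, seed=5)
        assert np.array_equal(a.perm, b.perm)
        c = pm.spin_permutations(geom120, 50, seed=6)
        assert not np.array_equal(a.perm, c.perm)

    def test_rows_cover_valid_indices(self, geom120):
        nulls = pm.spin_permutations(geom120, 30, seed=1)
        assert nulls.perm.min() >= 0 and nulls.perm.max() < len(geom120)

    def test_spins_preserve_spatial_autocorrelation(self, geom120):
        """Spun versions of a smooth map keep its Moran's I (within 25%),
        while naive shuffles destroy it."""
        ccfg = pm.CohortConfig(n_regions=120, atrophy_regions=frozenset(range(1, 31)))
        ecfg = pm.ExpressionConfig(n_genes=5, planted_set_size=5,
                                   smoothing_length=0.5, planted_coupling=0.0,
                                   seed=3)
        y = pm.true_interaction_map(ccfg, geom120)
        expr, _ = pm.generate_expression(ecfg, geom120, y)
        smooth = expr.iloc[:, 0].to_numpy()
        w = knn_weight_matrix(sphere_coords(geom120), k=6)
        i_orig = morans_i(smooth, w)
        assert i_orig > 0.3  # the map is genuinely smooth
        nulls = pm.spin_permutations(geom120, 100, seed=4)
        i_spun = np.mean([morans_i(smooth[p], w) for p in nulls.perm])
        assert abs(i_spun - i_orig) / i_orig < 0.25
        rng = np.random.default_rng(5)
        i_shuf = np.mean([morans_i(rng.permutation(smooth), w)
                          for _ in range(100)])
        assert abs(i_shuf) < 0.1

    def test_single_hemisphere_required(self, geom120):
        mixed = geom120.copy()
        mixed.loc[mixed.index[:5], "hemisphere"] = "R"
        with pytest.raises(ValueError, match="hemisphere"):
            pm.spin_permutations(mixed, 10, seed=0)


class TestLVSignificance:
    def test_gene_column_outcome_is_significant(self, planted_pls_data, geom120):
        expr, planted, _ = planted_pls_data
        y = expr[planted[0]].to_numpy()
        model = pm.pls_fit(expr, y, n_components=1)
        nulls = pm.spin_permutations(geom120, 1000, seed=2)
        p = pm.lv_significance(model, expr, y, nulls)
        assert p[0] <= 0.01

    def test_permutation_floor_attained(self, geom120):
        """With a y that is itself a gene map, the spin p-value reaches its
        add-one floor 1/(n_perm + 1)."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 30))
        y = X[:, 0].copy()
        Xdf = as_df(X)
        model = pm.pls_fit(Xdf, y, n_components=1)
        nulls = pm.spin_permutations(geom120, 2000, seed=7)
        p = pm.lv_significance(model, Xdf, y, nulls)
        assert p[0] == pytest.approx(1 / 2001)
        assert p[0] > 0

    def test_multi_component_path_matches_vectorized(self, planted_pls_data, geom120):
        """The k=1 fast path and the generic loop agree, including on a weak
        outcome where null fractions genuinely vary."""
        expr, _, beta = planted_pls_data
        rng = np.random.default_rng(42)
        weak = rng.normal(size=len(beta))  # unrelated outcome
        nulls = pm.spin_permutations(geom120, 200, seed=8)
        for y in (beta, weak):
            m1 = pm.pls_fit(expr, y, n_components=1)
            p_fast = pm.lv_significance(m1, expr, y, nulls)
            m2 = pm.pls_fit(expr, y, n_components=2)
            p_loop = pm.lv_significance(m2, expr, y, nulls)
            assert p_fast[0] == pytest.approx(p_loop[0])


class TestBootstrap:
    def test_defining_gene_attains_max_ratio(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 30))
        y = X[:, 4].copy()
        boot = pm.bootstrap_gene_weights(as_df(X), y, (1,), n_boot=200, seed=1)
        assert np.argmax(boot.ratio[:, 0]) == 4

    def test_ratios_stable_across_seeds(self, planted_pls_data):
        expr, _, beta = planted_pls_data
        b1 = pm.bootstrap_gene_weights(expr, beta, (1,), n_boot=1000, seed=1)
        b2 = pm.bootstrap_gene_weights(expr, beta, (1,), n_boot=1000, seed=2)
        top = np.argsort(b1.ratio[:, 0])[-10:]
        assert np.abs(b1.ratio[top, 0] - b2.ratio[top, 0]).max() < 1.0

    def test_pure_noise_tail_calibrated(self):
        """Under a pure-noise outcome, |bootstrap ratio| > 3 occurs for
        roughly the normal-tail fraction (0.27%) of genes."""
        rng = np.random.default_rng(10)
        n_hits = n_genes = 0
        for rep in range(30):
            X = rng.normal(size=(120, 150))
            y = rng.normal(size=120)
            boot = pm.bootstrap_gene_weights(as_df(X), y, (1,), n_boot=300,
                                             seed=rep)
            n_hits += (np.abs(boot.ratio[:, 0]) > 3).sum()
            n_genes += boot.ratio.shape[0]
        assert n_hits / n_genes < 0.003 + 0.005

    def test_ranked_scores_sorted_descending(self, planted_pls_data):
        expr, _, beta = planted_pls_data
        boot = pm.bootstrap_gene_weights(expr, beta, (1,), n_boot=100, seed=3)
        s = boot.ranked_scores(1)
        assert (np.diff(s.to_numpy()) <= 0).all()
        assert set(s.index) == set(expr.columns)
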