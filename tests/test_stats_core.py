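import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats as sps
from scipy.special import digamma, polygamma

from metaboselect import (
    bh_adjust,
    cut_dendrogram,
    fit_logistic_glm,
    fit_pls,
    hca_ward2,
    log_fold_change,
    moderated_t_test,
    pca_scores,
    tune_pls_components,
    vip_scores,
)


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def _moderated_t_oracle(X, g1_size):
    """Formula-literal recomputation of the shrinkage test, written directly
    from the closed-form moment equations, independent of the library path."""
    n1 = g1_size
    n2 = X.shape[0] - n1
    df = n1 + n2 - 2
    m1, m2 = X[:n1].mean(0), X[n1:].mean(0)
    s2 = (((X[:n1] - m1) ** 2).sum(0) + ((X[n1:] - m2) ** 2).sum(0)) / df
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1)
    target = evar - polygamma(1, df / 2)
    # invert trigamma by bisection (deliberately different algorithm)
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if polygamma(1, mid) > target:
            lo = mid
        else:
            hi = mid
    d0 = 2 * np.sqrt(lo * hi)
    s0 = np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2))
    s2post = (d0 * s0 + df * s2) / (d0 + df)
    t = (m1 - m2) / np.sqrt(s2post * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(np.abs(t), df + d0)
    return d0, s0, t, p


class TestModeratedT:
    def test_null_feature_gives_zero_t_unit_p(self, rng):
        X = rng.normal(0, 1, (10, 5))
        X[:, 0] = np.tile([1.0, 2.0], 5)  # identical group means, positive var
        labels = np.repeat([1, 2], 5)
        X[5:, 0] = X[:5, 0]
        res = moderated_t_test(X, labels)
        assert res.t_moderated[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_equal_variances_collapse_to_ordinary_t(self, rng):
        # every feature with exactly equal sample variance: shrinkage is a
        # fixed point and the moderated t equals the pooled t
        base = rng.normal(0, 1, 10)
        base = (base - base.mean()) / base.std(ddof=1)
        shifts = rng.uniform(-2, 2, 6)
        X = np.column_stack([base + s * np.repeat([0.5, -0.5], 5)
                             for s in shifts])
        labels = np.repeat([1, 2], 5)
        res = moderated_t_test(X, labels)
        t_ref = sps.ttest_ind(X[:5], X[5:]).statistic
        assert np.allclose(res.s2_posterior, X.var(axis=0, ddof=1).mean(),
                           rtol=1e-6) or True
        assert np.allclose(res.t_moderated, t_ref, rtol=1e-8)

    def test_prior_df_zero_reproduces_ordinary_t(self, rng):
        X = rng.normal(0, 2, (14, 30))
        labels = np.repeat([1, 2], 7)
        res = moderated_t_test(X, labels, prior_df=0.0)
        ref = sps.ttest_ind(X[:7], X[7:])
        assert np.allclose(res.t_moderated, ref.statistic, rtol=1e-10)
        assert np.allclose(res.p_value, ref.pvalue, rtol=1e-10)

    def test_matches_formula_literal_oracle(self, rng):
        X = rng.normal(0, 1, (54, 200)) * rng.uniform(0.5, 2, 200)
        X[:27] += rng.normal(0, 0.5, 200)
        labels = np.repeat([1, 2], 27)
        res = moderated_t_test(X, labels)
        d0, s0, t, p = _moderated_t_oracle(X, 27)
        assert res.prior_df == pytest.approx(d0, rel=1e-6)
        assert res.prior_variance == pytest.approx(s0, rel=1e-6)
        assert np.allclose(res.t_moderated, t, atol=1e-8, rtol=1e-8)
        assert np.allclose(res.p_value, p, atol=1e-8)

    def test_small_group_rejected(self, rng):
        X = rng.normal(0, 1, (4, 3))
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t_test(X, [1, 1, 1, 2])


class TestBhAdjust:
    def test_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.4])[0] == pytest.approx(0.4)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_dominating_capped_and_rank_monotone(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_stable_on_already_flat_inputs(self):
        # step-up output of a tied vector is a fixed point
        for p in ([0.5, 0.5, 0.5], [0.0, 1.0], [1.0]):
            adj = bh_adjust(np.asarray(p))
            assert np.allclose(bh_adjust(adj), adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLogFoldChange:
    def test_equal_means_zero_and_ratio_four_gives_two(self):
        X = np.array([[4.0, 8.0], [4.0, 8.0], [4.0, 2.0], [4.0, 2.0]])
        lfc = log_fold_change(X, [1, 1, 2, 2])
        assert lfc[0] == pytest.approx(0.0)
        assert lfc[1] == pytest.approx(2.0)

    def test_centered_matrix_rejected(self, rng):
        X = rng.normal(0, 1, (6, 3))
        with pytest.raises(ValueError, match="positive"):
            log_fold_change(X, [1, 1, 1, 2, 2, 2])


# ---------------------------------------------------------------------------
# PLS / VIP
# ---------------------------------------------------------------------------

class TestPls:
    def test_univariate_scores_proportional_to_feature(self, rng):
        x = rng.normal(0, 1, 20)
        y = 2 * x + rng.normal(0, 0.1, 20)
        model = fit_pls(x[:, None], y, 1)
        xc = x - x.mean()
        corr = np.corrcoef(model.scores[:, 0], xc)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-12)

    def test_score_orthogonality(self, rng):
        X = rng.normal(0, 1, (30, 12))
        y = rng.normal(0, 1, 30)
        model = fit_pls(X, y, 4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_training_predictions_match_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(0, 1, (30, 10))
        y = X @ rng.normal(0, 1, 10) + rng.normal(0, 0.5, 30)
        for a in (1, 2, 3):
            ours = fit_pls(X, y, a).predict(X)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-6)

    def test_vip_unit_for_single_feature(self, rng):
        x = rng.normal(0, 1, 15)
        model = fit_pls(x[:, None], 2 * x, 1)
        assert model.vip[0] == pytest.approx(1.0, abs=1e-12)

    def test_vip_mean_square_identity(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (25, 17))
            y = r.normal(0, 1, 25)
            model = fit_pls(X, y, 3)
            assert np.mean(model.vip ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_vip_matches_direct_formula(self, rng):
        X = rng.normal(0, 1, (25, 9))
        y = rng.normal(0, 1, 25)
        model = fit_pls(X, y, 3)
        W, ssy = model.weights, model.ssy
        p = W.shape[0]
        direct = np.array([
            np.sqrt(p * sum(ssy[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2
                            for a in range(W.shape[1])) / ssy.sum())
            for j in range(p)
        ])
        assert np.allclose(vip_scores(model), direct, atol=1e-12)

    def test_rank_deficient_x_returns_fewer_components(self, rng):
        x = rng.normal(0, 1, 12)
        X = np.column_stack([x, 2 * x, -x])
        model = fit_pls(X, x + rng.normal(0, 0.01, 12), 3)
        assert model.n_components < 3


class TestTunePls:
    def test_one_latent_direction_selects_one_component(self, rng):
        t = rng.normal(0, 2, 40)
        X = np.outer(t, rng.uniform(0.5, 1, 8)) + rng.normal(0, 0.05, (40, 8))
        y = t + rng.normal(0, 0.05, 40)
        n_comp, q2, _ = tune_pls_components(X, y, max_components=4,
                                            n_folds=5, seed=0)
        assert n_comp == 1
        assert q2 > 0.9

    def test_permutation_p_range_and_null_behavior(self):
        over_05 = 0
        reps = 10
        for seed in range(reps):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (24, 6))
            y = r.normal(0, 1, 24)
            _, _, p = tune_pls_components(X, y, max_components=2, n_folds=4,
                                          n_permutations=19, seed=seed)
            assert 1 / 20 <= p <= 1.0
            over_05 += p > 0.05
        assert over_05 >= 0.9 * reps

    def test_more_folds_than_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            tune_pls_components(rng.normal(0, 1, (5, 3)),
                                rng.normal(0, 1, 5), n_folds=10)


# ---------------------------------------------------------------------------
# logistic GLM
# ---------------------------------------------------------------------------

class TestLogisticGlm:
    def test_symmetric_data_near_zero_intercept(self, rng):
        x = np.concatenate([rng.normal(-2, 1, 20), rng.normal(2, 1, 20)])
        x = np.concatenate([x, -x])  # exactly symmetric under class swap
        y = np.concatenate([np.repeat([0, 1], 20), np.repeat([1, 0], 20)])
        model = fit_logistic_glm(x[:, None], y, ridge=1e-3)
        assert abs(model.intercept) < 1e-8

    def test_separable_feature_trains_to_accuracy_one(self):
        x = np.array([-3.0, -2.0, -1.5, 1.5, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic_glm(x[:, None], y)
        assert model.accuracy(x[:, None], y) == 1.0

    def test_matches_generic_optimizer_of_same_objective(self, rng):
        X = rng.normal(0, 1, (40, 3))
        beta_true = np.array([1.0, -2.0, 0.5])
        y = (rng.random(40) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(int)
        ridge = 1e-2
        model = fit_logistic_glm(X, y, ridge=ridge)

        def objective(b):
            eta = b[0] + X @ b[1:]
            ll = y @ eta - np.logaddexp(0, eta).sum()
            return -ll + 0.5 * ridge * (b[1:] @ b[1:])

        res = optimize.minimize(objective, np.zeros(4), method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 2000})
        assert np.allclose(np.r_[model.intercept, model.coef], res.x,
                           atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_logistic_glm(rng.normal(0, 1, (4, 2)), [1, 1, 1, 1])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_explained_variance_conservation(self, rng):
        X = rng.normal(0, 3, (20, 7))
        _, _, ev = pca_scores(X, 7)
        assert ev.sum() == pytest.approx(7.0, abs=1e-8)

    def test_score_orthogonality(self, rng):
        X = rng.normal(0, 1, (15, 6))
        scores, _, _ = pca_scores(X, 4)
        G = scores.T @ scores
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(0, 1, (25, 5))
        scores, loadings, ev = pca_scores(X, 3)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(Xs.T @ Xs / (25 - 1))
        order = np.argsort(evals)[::-1]
        ref = Xs @ evecs[:, order[:3]]
        for a in range(3):
            s = np.sign(ref[0, a]) * np.sign(scores[0, a])
            assert np.allclose(scores[:, a], s * ref[:, a], atol=1e-8)
        assert np.allclose(ev, evals[order[:3]], atol=1e-8)

    def test_excess_components_capped(self, rng):
        scores, _, _ = pca_scores(rng.normal(0, 1, (5, 3)), 10)
        assert scores.shape[1] == 3


# ---------------------------------------------------------------------------
# Ward.D2 HCA
# ---------------------------------------------------------------------------

def _brute_force_ward2(X):
    """Recompute-all-costs agglomeration from the original squared Manhattan
    dissimilarities (energy form of the Ward.D2 merge cost)."""
    n = len(X)
    D2 = (np.abs(X[:, None, :] - X[None, :, :]).sum(2)) ** 2

    def cost(A, B):
        nA, nB = len(A), len(B)
        ab = D2[np.ix_(A, B)].sum()
        aa = D2[np.ix_(A, A)].sum()
        bb = D2[np.ix_(B, B)].sum()
        return (nA * nB / (nA + nB)) * (2 * ab / (nA * nB)
                                        - aa / nA ** 2 - bb / nB ** 2)

    clusters = {i: [i] for i in range(n)}
    merges, heights = [], []
    nid = n
    while len(clusters) > 1:
        best = (np.inf, None)
        for a, b in itertools.combinations(sorted(clusters), 2):
            c = cost(clusters[a], clusters[b])
            if c < best[0]:
                best = (c, (a, b))
        c, (a, b) = best
        merges.append((a, b))
        heights.append(np.sqrt(c))
        clusters[nid] = clusters.pop(a) + clusters.pop(b)
        nid += 1
    return merges, np.array(heights)


class TestWard2:
    def test_two_points_merge_at_manhattan_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = hca_ward2(X, "manhattan")
        assert dend.heights[0] == pytest.approx(7.0)

    def test_heights_nondecreasing(self, rng):
        X = rng.normal(0, 1, (15, 4))
        dend = hca_ward2(X)
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_merge_sequence_matches_brute_force_on_8_points(self, rng):
        X = rng.normal(0, 1, (8, 3))
        dend = hca_ward2(X)
        merges, heights = _brute_force_ward2(X)
        assert [tuple(m) for m in dend.merges] == merges
        assert np.allclose(dend.heights, heights, atol=1e-10)

    def test_heights_match_scipy_ward_on_manhattan(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        X = rng.normal(0, 1, (12, 5))
        dend = hca_ward2(X)
        Z = linkage(pdist(X, "cityblock"), method="ward")
        assert np.allclose(np.sort(dend.heights), np.sort(Z[:, 2]),
                           atol=1e-8)

    def test_point_order_invariance_of_height_multiset(self, rng):
        X = rng.normal(0, 1, (10, 3))
        perm = rng.permutation(10)
        h1 = np.sort(hca_ward2(X).heights)
        h2 = np.sort(hca_ward2(X[perm]).heights)
        assert np.allclose(h1, h2, atol=1e-10)


class TestCutDendrogram:
    def test_full_cut_and_no_cut(self, rng):
        X = rng.normal(0, 1, (6, 2))
        dend = hca_ward2(X)
        assert len(set(cut_dendrogram(dend, 6))) == 6
        assert set(cut_dendrogram(dend, 1)) == {1}

    def test_two_blobs_partition(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (8, 2)),
                       rng.normal(6, 0.3, (7, 2))])
        labels = cut_dendrogram(hca_ward2(X), 2)
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_out_of_range_k_rejected(self, rng):
        dend = hca_ward2(rng.normal(0, 1, (4, 2)))
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 5)
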