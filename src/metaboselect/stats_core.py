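"""Self-contained statistics behind classification and marker selection.

Implements, from first principles, every statistic the selection procedure
relies on:

* a two-group **moderated t-test** with empirical-Bayes variance shrinkage —
  per-feature residual variances are shrunk toward a prior ``s0²`` with
  prior degrees of freedom ``d0``, both estimated by moment-matching the
  scaled-F marginal distribution of the log sample variances;
* **Benjamini–Hochberg** step-up adjustment of p-values;
* **log2 fold change** between groups on the raw intensity scale;
* **PLS1 by NIPALS** with per-component explained response variance and the
  **VIP** (variable importance in projection) statistic, plus Q²-based
  component tuning with a permutation test;
* a ridge-stabilized **logistic GLM** fitted by iteratively reweighted
  least squares;
* **PCA** via singular value decomposition of the autoscaled matrix;
* agglomerative **Ward.D2** clustering on Manhattan distances via the
  Lance–Williams recurrence on squared dissimilarities.

scipy, scikit-learn and statsmodels offer equivalents of several of these;
they are used as independent cross-checks in the test suite, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma

__all__ = [
    "ModeratedTestResult",
    "PlsModel",
    "LogisticModel",
    "Dendrogram",
    "moderated_t_test",
    "bh_adjust",
    "log_fold_change",
    "fit_pls",
    "vip_scores",
    "tune_pls_components",
    "fit_logistic_glm",
    "pca_scores",
    "hca_ward2",
    "cut_dendrogram",
    "stratified_folds",
]

logger = logging.getLogger("metaboselect")


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x ≈ 0.5 + 1/y and the update in terms of
    1/x, which is stable over the whole range.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _as_binary_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    return labels == levels[0], labels == levels[1]


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTestResult:
    """Per-feature moderated two-group test with shrinkage diagnostics."""

    mean_difference: np.ndarray
    t_moderated: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray
    s2_posterior: np.ndarray
    prior_df: float        # d0 (may be inf)
    prior_variance: float  # s0^2
    residual_df: float

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_difference": self.mean_difference,
                "t_moderated": self.t_moderated,
                "p_value": self.p_value,
                "p_adjusted": self.p_adjusted,
                "s2_posterior": self.s2_posterior,
            },
            index=index,
        )


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) of the scaled-F marginal of sample variances.

    With z = log s², E z = log s0² + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2)
    and Var z = ψ'(d/2) + ψ'(d0/2); the excess of the empirical variance of
    z over ψ'(d/2) identifies d0 through the trigamma inverse.
    """
    ok = s2 > 0
    if not ok.any():
        raise ValueError("no positive residual variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(_trigamma(df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: all true variances equal; the common value
        # is estimated by the plain mean, making shrinkage a fixed point
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    return d0, s0_sq


def moderated_t_test(matrix: np.ndarray, labels, prior_df: float | None = None
                     ) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-group t-test, feature by feature.

    Each feature gets a least-squares two-group fit; the residual variances
    are shrunk toward the moment-matched prior, the moderated statistic is
    referred to a t distribution on ``d + d0`` degrees of freedom, and
    BH-adjusted p-values are attached.

    Parameters
    ----------
    matrix
        ``(n_samples, n_features)``; typically log2 corrected intensities.
    labels
        Binary group label per sample; each group needs ≥ 2 members.
    prior_df
        Override the estimated prior degrees of freedom (``0`` reproduces
        the ordinary pooled t-test exactly; mainly for validation).
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    g1, g2 = _as_binary_groups(labels)
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 samples (got {n1}, {n2})")
    df = float(n1 + n2 - 2)
    m1 = X[g1].mean(axis=0)
    m2 = X[g2].mean(axis=0)
    ss = ((X[g1] - m1) ** 2).sum(axis=0) + ((X[g2] - m2) ** 2).sum(axis=0)
    s2 = ss / df
    diff = m1 - m2

    if prior_df is None:
        if (s2 == 0).all():
            logger.warning("all residual variances are zero; "
                           "falling back to the ordinary t-test")
            d0, s0_sq = 0.0, 0.0
        else:
            d0, s0_sq = _fit_f_dist(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0,
                                                 np.sign(diff) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    return ModeratedTestResult(
        mean_difference=diff, t_moderated=t, p_value=p,
        p_adjusted=bh_adjust(p), s2_posterior=s2_post,
        prior_df=d0, prior_variance=s0_sq, residual_df=df,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def log_fold_change(matrix: np.ndarray, labels) -> np.ndarray:
    """Per-feature log2 ratio of group-1 to group-2 mean intensity.

    Must be computed on the positive (corrected, unscaled) intensity scale;
    a nonpositive group mean is an error.
    """
    X = np.asarray(matrix, dtype=float)
    g1, g2 = _as_binary_groups(labels)
    m1 = X[g1].mean(axis=0)
    m2 = X[g2].mean(axis=0)
    if (m1 <= 0).any() or (m2 <= 0).any():
        raise ValueError("log fold change needs positive group means; "
                         "was the matrix already centered?")
    return np.log2(m1 / m2)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) and VIP
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """A fitted NIPALS PLS1 model.

    ``weights`` W, ``loadings`` P are features × A; ``y_loadings`` q and
    ``ssy`` (explained sum of squares of y) are per component; ``scores``
    T is samples × A with mutually orthogonal columns.
    """

    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    ssy: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    n_components: int
    q2: float | None = None
    r2y: float | None = None
    vip: np.ndarray | None = None

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector b with yhat = y_mean + (X − x_mean) b."""
        a = self.n_components if n_components is None else n_components
        W, P, q = self.weights[:, :a], self.loadings[:, :a], self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.coefficients(n_components)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Fit a PLS1 model by NIPALS with X-deflation.

    ``X`` is expected on the autoscaled scale and ``y`` is the class
    response (+1/−1); both are centered internally so predictions work on
    the original inputs.  If the deflated matrix runs out of rank the model
    returns fewer components with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_components = min(n_components, n - 1 if n > 1 else 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    eps = np.finfo(float).eps
    a = 0
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e3 * eps * max(1.0, np.abs(yd).max()):
            logger.warning("PLS rank exhausted after %d components", a)
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e3 * eps:
            logger.warning("PLS rank exhausted after %d components", a)
            break
        qa = float(yd @ t) / tt
        pa = (Xd.T @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        ssy[a] = qa * qa * tt
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t
        a += 1
    if a == 0:
        raise ValueError("no PLS component could be extracted (constant y?)")
    model = PlsModel(
        weights=W[:, :a], loadings=P[:, :a], y_loadings=q[:a],
        scores=T[:, :a], ssy=ssy[:a], x_mean=x_mean, y_mean=y_mean,
        n_components=a,
    )
    tss = float(((y - y_mean) ** 2).sum())
    model.r2y = float(ssy[:a].sum() / tss) if tss > 0 else np.nan
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )``; the mean
    of VIP² over features is exactly 1.
    """
    ssy = model.ssy
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("model explains no response variance (total SSY = 0)")
    W = model.weights
    p = W.shape[0]
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W ** 2) / wnorm2
    return np.sqrt(p * (contrib @ ssy) / total)


def stratified_folds(labels, n_folds: int, rng: np.random.Generator
                     ) -> list[np.ndarray]:
    """Seeded stratified k-fold partition of sample indices.

    Works for class labels (each class spread evenly over folds) and,
    through the running fold-id rotation, degrades gracefully to balanced
    folds when every level is a singleton (continuous responses).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds > n:
        raise ValueError("more folds than samples")
    assignment = np.empty(n, dtype=int)
    start = 0
    for level in np.unique(labels):
        idx = np.flatnonzero(labels == level)
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = (np.arange(len(idx)) + start) % n_folds
        start += len(idx)
    return [np.flatnonzero(assignment == f) for f in range(n_folds)]


def tune_pls_components(X: np.ndarray, y: np.ndarray, max_components: int = 5,
                        n_folds: int = 10, n_permutations: int = 0,
                        seed: int = 0) -> tuple[int, float, float | None]:
    """Choose the PLS component count by cross-validated Q².

    Q²(a) = 1 − PRESS(a)/TSS over seeded stratified folds; the component
    count maximizing Q² wins.  With ``n_permutations`` > 0 a label
    permutation test is run: p = (1 + #{Q²_perm ≥ Q²_obs}) / (B + 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n_folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)

    def cv_q2(y_use: np.ndarray, folds) -> tuple[int, float]:
        a_max = min(max_components, n - max(len(f) for f in folds) - 1, X.shape[1])
        a_max = max(a_max, 1)
        press = np.zeros(a_max)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            model = fit_pls(X[train_idx], y_use[train_idx], a_max)
            for a in range(1, model.n_components + 1):
                resid = y_use[test_idx] - model.predict(X[test_idx], a)
                press[a - 1] += float(resid @ resid)
            # rank-deficient fits: unreachable components inherit the last
            for a in range(model.n_components + 1, a_max + 1):
                resid = y_use[test_idx] - model.predict(X[test_idx])
                press[a - 1] += float(resid @ resid)
        tss = float(((y_use - y_use.mean()) ** 2).sum())
        q2 = 1.0 - press / tss
        best = int(np.argmax(q2))
        return best + 1, float(q2[best])

    folds = stratified_folds(y, n_folds, rng)
    n_comp, q2 = cv_q2(y, folds)
    perm_p = None
    if n_permutations > 0:
        hits = 0
        for _ in range(n_permutations):
            y_perm = y[rng.permutation(n)]
            perm_folds = stratified_folds(y_perm, n_folds, rng)
            _, q2_perm = cv_q2(y_perm, perm_folds)
            hits += q2_perm >= q2
        perm_p = (1.0 + hits) / (n_permutations + 1.0)
    return n_comp, q2, perm_p


# ---------------------------------------------------------------------------
# logistic GLM (ridge-stabilized IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Penalized-likelihood logistic fit; predicts class by p ≥ 0.5."""

    intercept: float
    coef: np.ndarray
    classes: np.ndarray
    ridge: float
    deviance: float
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.predict_proba(X) >= 0.5,
                        self.classes[1], self.classes[0])

    def accuracy(self, X: np.ndarray, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def fit_logistic_glm(X: np.ndarray, y, ridge: float = 1e-3,
                     max_iter: int = 200, tol: float = 1e-10) -> LogisticModel:
    """Fit a binary logistic GLM by iteratively reweighted least squares.

    The objective is the negative log-likelihood plus ``ridge/2 · ‖β‖²``
    on the slopes (intercept unpenalized); the small default ridge keeps
    the fit finite on separable data.  Raises on non-convergence, carrying
    the last deviance in the message.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"two classes required, got {list(classes)}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs >= 2 samples")
    t = (y == classes[1]).astype(float)
    n, p = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0

    def pen_deviance(b: np.ndarray) -> float:
        eta = Z @ b
        ll = float(t @ eta - np.logaddexp(0, eta).sum())
        return -2.0 * ll + float(pen @ b**2)

    deviance = pen_deviance(beta)
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = Z.T @ (t - mu) - pen * beta
        H = (Z.T * w) @ Z + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # safeguarded Newton: halve the step until the objective improves
        factor = 1.0
        for _ in range(40):
            new_dev = pen_deviance(beta + factor * step)
            if new_dev <= deviance + 1e-12 * (abs(deviance) + 1):
                break
            factor *= 0.5
        beta = beta + factor * step
        if (np.abs(factor * step).max() < tol
                or abs(deviance - new_dev) < tol * (abs(new_dev) + 1)):
            return LogisticModel(float(beta[0]), beta[1:], classes, ridge,
                                 new_dev, it)
        deviance = new_dev
    raise RuntimeError(
        f"logistic IRLS did not converge in {max_iter} iterations "
        f"(last penalized deviance {deviance:.6g})"
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(matrix: np.ndarray, n_components: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-component scores of a data matrix.

    The matrix is centered and unit-variance scaled internally (constant
    features are dropped), then decomposed by SVD; scores are the left
    singular vectors times the singular values, and the explained variances
    sum to the number of non-constant features.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    max_comp = min(n, int(keep.sum()))
    if n_components > max_comp:
        logger.warning("n_components capped at %d", max_comp)
        n_components = max_comp
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = (U * S)[:, :n_components]
    loadings = Vt[:n_components].T
    explained = (S ** 2) / (n - 1)
    return scores, loadings, explained[:n_components]


# ---------------------------------------------------------------------------
# Ward.D2 hierarchical clustering on Manhattan distances
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomeration record: n−1 merges with non-decreasing heights.

    ``merges[i]`` holds the two cluster indices merged at step ``i`` —
    leaves are 0..n−1, the cluster created at step ``i`` is ``n + i``.
    """

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    n_leaves: int
    leaf_order: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.leaf_order is None:
            self.leaf_order = self._compute_leaf_order()

    def _compute_leaf_order(self) -> np.ndarray:
        children = {self.n_leaves + i: tuple(m) for i, m in enumerate(self.merges)}
        order: list[int] = []
        root = self.n_leaves + len(self.merges) - 1

        def walk(node: int) -> None:
            stack = [node]
            while stack:
                cur = stack.pop()
                if cur < self.n_leaves:
                    order.append(cur)
                else:
                    a, b = children[cur]
                    stack.extend((b, a))

        if len(self.merges):
            walk(root)
        else:
            order = list(range(self.n_leaves))
        return np.asarray(order)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n−1) × 4 linkage matrix."""
        sizes = np.ones(self.n_leaves + len(self.merges))
        Z = np.zeros((len(self.merges), 4))
        for i, (a, b) in enumerate(self.merges):
            sizes[self.n_leaves + i] = sizes[a] + sizes[b]
            Z[i] = (a, b, self.heights[i], sizes[self.n_leaves + i])
        return Z


def _pairwise_distance(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "manhattan":
        return np.abs(points[:, None, :] - points[None, :, :]).sum(axis=2)
    if metric == "euclidean":
        d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2)
    raise ValueError(f"unsupported metric {metric!r}")


def hca_ward2(points: np.ndarray, metric: str = "manhattan") -> Dendrogram:
    """Agglomerative clustering by the Ward.D2 convention.

    The Lance–Williams recurrence is applied to the *squared* input
    dissimilarities (here Manhattan distances between samples) and merge
    heights are reported on the original scale; this is the convention of
    the "ward.D2" linkage.  Ties are broken toward the smaller cluster
    index, making the merge sequence deterministic.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two points")
    n = X.shape[0]
    D2 = _pairwise_distance(X, metric) ** 2
    np.fill_diagonal(D2, np.inf)
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    index_of = {i: i for i in range(n)}  # cluster id -> row in D2
    rows = {i: i for i in range(n)}      # row in D2 -> cluster id
    merges = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    next_id = n
    for step in range(n - 1):
        # find the minimum over active rows, deterministic tie-break
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                ra, rb = index_of[active[ai]], index_of[active[bi]]
                d = D2[ra, rb]
                if d < best[0]:
                    best = (d, active[ai], active[bi])
        d2_min, ca, cb = best
        heights[step] = np.sqrt(max(d2_min, 0.0))
        merges[step] = (ca, cb)
        ra, rb = index_of[ca], index_of[cb]
        na, nb = size[ca], size[cb]
        # Lance-Williams update for Ward on squared dissimilarities
        for c in active:
            if c in (ca, cb):
                continue
            rc = index_of[c]
            nc = size[c]
            d_new = ((na + nc) * D2[ra, rc] + (nb + nc) * D2[rb, rc]
                     - nc * d2_min) / (na + nb + nc)
            D2[ra, rc] = D2[rc, ra] = d_new
        D2[rb, :] = np.inf
        D2[:, rb] = np.inf
        size[next_id] = na + nb
        index_of[next_id] = ra
        active.remove(ca)
        active.remove(cb)
        active.append(next_id)
        next_id += 1
    return Dendrogram(merges=merges, heights=heights, n_leaves=n)


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels obtained by removing the k−1 highest merges.

    Returns integer labels 1..k; cluster numbers follow the smallest leaf
    index they contain (deterministic).
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(dend.merges)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (a, b) in enumerate(dend.merges[: n - k]):
        ra, rb, rn = find(int(a)), find(int(b)), n + i
        parent[ra] = parent[rb] = rn
    roots = [find(i) for i in range(n)]
    label_of: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    for leaf in range(n):
        r = roots[leaf]
        if r not in label_of:
            label_of[r] = len(label_of) + 1
        labels[leaf] = label_of[r]
    return labels
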