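"""Downstream statistical inference.

Covariate-adjusted partial correlations with Benjamini-Hochberg FDR
control, first-pair canonical correlation analysis with structure
coefficients and permutation p-values, MOCA-based cognitive-status
stratification with independent-sample t-tests, and repeated k-means
classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "PartialCorrResult",
    "CCAResult",
    "partial_correlation",
    "bh_fdr",
    "cca_first_pair",
    "permutation_pvalue",
    "stratify_moca",
    "independent_t_test",
    "kmeans_classification_accuracy",
]

MOCA_LOW_CUTOFF = 18.0  # scores strictly below -> impaired extreme (MOCA-)
MOCA_HIGH_CUTOFF = 25.0  # scores at/above -> intact extreme (MOCA+)


@dataclass
class PartialCorrResult:
    """Partial correlation after removing covariate effects from both
    variables, with a t-distribution p-value on n - c - 2 degrees of
    freedom."""

    rho: float
    p_value: float
    n_effective: int
    covariates: list[str]
    method: str


@dataclass
class CCAResult:
    """First canonical pair: weights, unit-variance variates, canonical
    correlation (nonnegative by sign convention), per-variable structure
    coefficients, and an optional permutation p-value."""

    weights_x: np.ndarray
    weights_y: np.ndarray
    variates_u: np.ndarray
    variates_v: np.ndarray
    r: float
    structure_x: np.ndarray
    structure_y: np.ndarray
    p_perm: float | None = None
    n_permutations: int = 0


def _listwise(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    """Drop rows where any input has a missing value."""
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a).all(axis=1) if a.ndim == 2 else np.isfinite(a)
    return tuple(np.asarray(a, dtype=float)[mask] for a in arrays)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of v after least-squares projection on [1, Z]."""
    design = np.column_stack([np.ones(len(v)), Z]) if Z.size else np.ones((len(v), 1))
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    method: str = "spearman",
    covariate_names: list[str] | None = None,
) -> PartialCorrResult:
    """Partial correlation of x and y controlling for the columns of Z.

    Missing rows are removed listwise.  For ``method="spearman"`` all
    variables are rank-transformed first (rank-residual partial Spearman);
    both variables are then residualized on [1, Z] by least squares and the
    residuals correlated.  The p-value uses the t distribution with
    n - c - 2 degrees of freedom, c the number of covariates.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if Z is None or np.size(Z) == 0:
        Z = np.empty((len(x), 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if not len(x) == len(y) == len(Z):
        raise ValueError("x, y and Z must have equal length")
    x, y, Z = _listwise(x, y, Z)
    n, c = len(x), Z.shape[1]
    if n <= c + 2:
        raise ValueError(f"need n > c + 2 complete rows (n={n}, c={c})")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        Z = np.column_stack([sps.rankdata(Z[:, j]) for j in range(c)]) if c else Z
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if rx.std() <= 1e-10 * (x.std() + 1) or ry.std() <= 1e-10 * (y.std() + 1):
        raise ValueError("zero-variance residual: variable lies in span of covariates")
    rho = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    df = n - c - 2
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrResult(
        rho=rho,
        p_value=p,
        n_effective=n,
        covariates=covariate_names or [f"z{j}" for j in range(c)],
        method=method,
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Rejects all hypotheses with p <= p_(k*) where k* = max{k : p_(k) <=
    k q / m}; adjusted p-values are m p_(k) / k with a monotone cumulative
    minimum from the largest p down.  Returns (reject mask, adjusted p).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    thresholds = np.arange(1, m + 1) * q / m
    passing = np.flatnonzero(ranked <= thresholds)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        k_star = passing[-1]
        reject[order[: k_star + 1]] = True
    return reject, adjusted


def cca_first_pair(
    X: np.ndarray,
    Y: np.ndarray,
    rng: np.random.Generator | None = None,
    n_permutations: int = 0,
) -> CCAResult:
    """First canonical pair of two variable sets.

    Columns are standardized internally and missing rows removed listwise.
    The pair (a, b) maximizing corr(Xa, Yb) is found via the SVD of the
    whitened cross-covariance; variates are scaled to unit (ddof=1)
    variance and signed so the canonical correlation is nonnegative.
    Structure coefficients are the correlations of each original column
    with its own set's variate.  If ``n_permutations > 0``, a permutation
    p-value for r is computed by shuffling the second variate's scores.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y):
        raise ValueError("X and Y must have equal row counts")
    X, Y = _listwise(X, Y)
    n, p, q = len(X), X.shape[1], Y.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q complete rows (n={n}, p={p}, q={q})")
    sx, sy = X.std(axis=0), Y.std(axis=0)
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("constant column; remove it before CCA")
    Xs = (X - X.mean(axis=0)) / sx
    Ys = (Y - Y.mean(axis=0)) / sy
    qx, rx_ = np.linalg.qr(Xs)
    qy, ry_ = np.linalg.qr(Ys)
    if (
        np.min(np.abs(np.diag(rx_))) < 1e-10 * n
        or np.min(np.abs(np.diag(ry_))) < 1e-10 * n
    ):
        raise ValueError("rank-deficient variable set; remove collinear columns")
    u_svd, svals, vt_svd = np.linalg.svd(qx.T @ qy)
    r = float(np.clip(svals[0], 0.0, 1.0))
    a = np.linalg.solve(rx_, u_svd[:, 0])
    b = np.linalg.solve(ry_, vt_svd[0, :])
    u = Xs @ a
    v = Ys @ b
    # Unit-variance variates; deterministic overall sign: largest-|loading|
    # structure coefficient of the X set is made negative-free.
    u /= u.std(ddof=1)
    v /= v.std(ddof=1)
    a = np.linalg.lstsq(Xs, u, rcond=None)[0]
    b = np.linalg.lstsq(Ys, v, rcond=None)[0]
    if np.corrcoef(u, v)[0, 1] < 0:
        v, b = -v, -b
    sx_struct = np.array([np.corrcoef(Xs[:, j], u)[0, 1] for j in range(p)])
    if sx_struct[np.argmax(np.abs(sx_struct))] < 0:
        u, v, a, b = -u, -v, -a, -b
        sx_struct = -sx_struct
    sy_struct = np.array([np.corrcoef(Ys[:, j], v)[0, 1] for j in range(q)])
    result = CCAResult(
        weights_x=a,
        weights_y=b,
        variates_u=u,
        variates_v=v,
        r=r,
        structure_x=sx_struct,
        structure_y=sy_struct,
    )
    if n_permutations > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        result.p_perm = permutation_pvalue(u, v, B=n_permutations, rng=rng)
        result.n_permutations = n_permutations
    return result


def permutation_pvalue(
    u: np.ndarray,
    v: np.ndarray,
    B: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Two-sided permutation p-value for corr(u, v).

    The null distribution is built by permuting the indices of v and
    recomputing the correlation; p = (1 + #{|r_null| >= |r_obs|}) / (B + 1).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("u and v must have equal length")
    if B < 1:
        raise ValueError("need at least one permutation")
    if u.std() == 0 or v.std() == 0:
        raise ValueError("constant vector has no defined correlation")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = u.size
    uz = (u - u.mean()) / u.std()
    vz = (v - v.mean()) / v.std()
    r_obs = float(uz @ vz / n)
    perms = np.array([rng.permutation(n) for _ in range(B)])
    r_null = (vz[perms] @ uz) / n
    exceed = int(np.count_nonzero(np.abs(r_null) >= abs(r_obs)))
    return (1 + exceed) / (B + 1)


def stratify_moca(scores: np.ndarray) -> np.ndarray:
    """Cognitive-status labels from MOCA scores: ``MOCA-`` below 18,
    ``MOCA+`` at 25 or above, ``excluded`` otherwise (including missing)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.full(scores.shape, "excluded", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[scores < MOCA_LOW_CUTOFF] = "MOCA-"
        labels[scores >= MOCA_HIGH_CUTOFF] = "MOCA+"
    labels[~np.isfinite(scores)] = "excluded"
    return labels.astype(str)


def independent_t_test(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Independent-sample t-test (pooled variance by default; Welch with
    ``equal_var=False``).  Returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def kmeans_classification_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    iterations: int = 1000,
    k: int = 2,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Repeated 2-cluster k-means classification of cognitive-status groups.

    Only rows labelled MOCA+/MOCA- enter; features are standardized.  Each
    iteration runs k-means from a fresh random initialization; clusters map
    to labels by the assignment maximizing agreement, giving a per-iteration
    accuracy.  The reported accuracy is the modal per-iteration value, ties
    broken toward the larger value.  Returns (accuracy, per-iteration
    accuracies).
    """
    if k != 2:
        raise ValueError("cluster-to-label mapping is defined for k = 2")
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels)
    keep = np.isin(labels, ("MOCA+", "MOCA-")) & np.isfinite(features).all(axis=1)
    X = features[keep]
    y = (labels[keep] == "MOCA+").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both MOCA+ and MOCA- groups must be non-empty")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    accs = np.empty(iterations)
    for it in range(iterations):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        assign = km.labels_
        agree = np.mean(assign == y)
        accs[it] = max(agree, 1.0 - agree)
    vals, counts = np.unique(accs, return_counts=True)
    best = counts.max()
    accuracy = float(vals[counts == best].max())  # tie -> larger value
    return accuracy, accs
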