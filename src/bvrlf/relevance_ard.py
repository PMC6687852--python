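"""Automatic relevance determination of conductance factors.

A Gaussian-process regression with linear covariance
c(x, x') = sum_i sigma2_d,i x_i x'_i plus observation noise sigma2_r links
the eight conductance factors to a variability measure.  Hyperparameters
are optimized by type-II maximum likelihood (negative log marginal
likelihood minimized by L-BFGS on the log scale) on each of ten
cross-validation folds; per-feature variances are averaged over folds and
normalized to sum to one.  The sign of each feature's contribution comes
from interpreting the fit as linear regression with covariance C_ext:
s_i = sign(((C_ext^-1 X)^T y)_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize


@dataclass
class RelevanceDataset:
    """Standardized regression problem: features X (N x D), output y (N)."""

    x: np.ndarray
    y: np.ndarray
    y_mean: float = 0.0
    y_std: float = 1.0
    feature_names: tuple = ()

    @classmethod
    def from_raw(cls, x, y, feature_names=()) -> "RelevanceDataset":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or y.shape != (x.shape[0],):
            raise ValueError("X must be N x D and y length N")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("missing or non-finite entries")
        mu, sd = float(np.mean(y)), float(np.std(y))
        if sd == 0:
            raise ValueError("constant output cannot be standardized")
        return cls(x, (y - mu) / sd, mu, sd, tuple(feature_names))


@dataclass
class RelevanceResult:
    relevance: np.ndarray          # normalized over features, sums to 1
    sigma2_d: np.ndarray           # fold-averaged per-feature variances
    sigma2_r: float                # fold-averaged noise variance
    signs: np.ndarray              # per-feature sign in {-1, 0, +1}
    per_fold: np.ndarray           # n_folds x (D + 1), last column = noise
    explained_share: np.ndarray = None  # per-feature share incl. noise term
    feature_names: tuple = ()
    failed_folds: list = field(default_factory=list)


def _nlml(log_hyp, x, y):
    """Negative log marginal likelihood and gradient, log-scale hyperparams."""
    n, d = x.shape
    s2 = np.exp(np.clip(log_hyp, -40.0, 40.0))
    sigma2_d, sigma2_r = s2[:d], s2[d]
    c_ext = (x * sigma2_d) @ x.T + sigma2_r * np.eye(n)
    if not np.all(np.isfinite(c_ext)):
        return 1e12, np.zeros_like(log_hyp)
    try:
        cf = cho_factor(c_ext, lower=True)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(log_hyp)
    alpha = cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    nlml = 0.5 * logdet + 0.5 * y @ alpha + 0.5 * n * np.log(2.0 * np.pi)
    # gradient: dNLML/dtheta_j = 0.5 tr(C^-1 dC) - 0.5 alpha^T dC alpha,
    # with dC/dsigma2_i = x_i x_i^T and chain rule through the log scale
    cinv = cho_solve(cf, np.eye(n))
    grad = np.empty(d + 1)
    for i in range(d):
        xi = x[:, i]
        tr = xi @ cinv @ xi
        quad = (alpha @ xi) ** 2
        grad[i] = 0.5 * (tr - quad) * sigma2_d[i]
    grad[d] = 0.5 * (np.trace(cinv) - alpha @ alpha) * sigma2_r
    return nlml, grad


def _fit_fold(x, y, rng, n_restarts=3):
    d = x.shape[1]
    best = None
    inits = [np.zeros(d + 1)]
    inits += [rng.normal(0.0, 1.0, size=d + 1) for _ in range(n_restarts)]
    bounds = [(-30.0, 30.0)] * (d + 1)
    for x0 in inits:
        res = minimize(_nlml, x0, args=(x, y), jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        if best.success and best is res:
            break
    return np.exp(best.x), bool(best.success)


def fit_ard(data: RelevanceDataset, n_folds: int = 10, seed: int = 0,
            center: bool = False) -> RelevanceResult:
    """Fold-averaged ARD relevances, noise variance and contribution signs."""
    x = data.x - data.x.mean(axis=0) if center else data.x
    y = data.y
    n, d = x.shape
    if n <= d:
        raise ValueError("need more samples than features")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    per_fold = np.empty((n_folds, d + 1))
    failed = []
    for k, test_idx in enumerate(folds):
        train = np.setdiff1d(order, test_idx)
        hyp, ok = _fit_fold(x[train], y[train], rng)
        per_fold[k] = hyp
        if not ok:
            failed.append(k)
    sigma2_d = per_fold[:, :d].mean(axis=0)
    sigma2_r = float(per_fold[:, d].mean())
    total = sigma2_d.sum()
    relevance = sigma2_d / total if total > 0 else np.full(d, 1.0 / d)
    # share of output variance attributed to each feature, with the noise
    # variance in the denominator: well-posed even when no feature carries
    # signal (the feature-only normalization is then a ratio of near-zeros)
    contrib = sigma2_d * np.mean(x ** 2, axis=0)
    explained = contrib / (contrib.sum() + sigma2_r)
    signs = contribution_signs(x, y, sigma2_d, sigma2_r)
    return RelevanceResult(relevance, sigma2_d, sigma2_r, signs, per_fold,
                           explained, data.feature_names, failed)


def contribution_signs(x, y, sigma2_d, sigma2_r):
    """Per-feature contribution signs from the fitted extended covariance."""
    n = x.shape[0]
    c_ext = (x * sigma2_d) @ x.T + sigma2_r * np.eye(n)
    cf = cho_factor(c_ext, lower=True)
    proj = (cho_solve(cf, x)).T @ y
    signs = np.sign(proj)
    return signs.astype(int)


def ablation_relevance(data: RelevanceDataset, n_folds: int = 10,
                       seed: int = 0, center: bool = False) -> dict:
    """Refit ARD with one feature removed at a time.

    Returns {removed_feature_index: RelevanceResult with D-1 features};
    renormalized relevances expose co-dependencies between factors.
    """
    d = data.x.shape[1]
    out = {}
    names = data.feature_names or tuple(range(d))
    for i in range(d):
        keep = [j for j in range(d) if j != i]
        sub = RelevanceDataset(data.x[:, keep], data.y, data.y_mean,
                               data.y_std,
                               tuple(names[j] for j in keep))
        out[i] = fit_ard(sub, n_folds=n_folds, seed=seed, center=center)
    return out
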