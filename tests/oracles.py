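"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code with the package: pair-counting AUC, exhaustive threshold scans, a
double-loop greedy thinning reference, an IRLS (Newton) logistic solver and a
separately coded univariate Bayesian probit Gibbs sampler.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm


def pair_counting_auc(scores, labels) -> float:
    """AUC as explicit enumeration over positive-negative pairs, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_max_sens_spec(scores, labels) -> float:
    """Scan every observed score as a candidate threshold (rule: >=)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t, best_obj = None, -np.inf
    for t in sorted(set(scores.tolist())):
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        obj = sens + spec
        if obj > best_obj + 1e-12:
            best_obj, best_t = obj, t
    return float(best_t)


def greedy_thin_reference(lon, lat, radius_km) -> list[int]:
    """Greedy minimum-distance thinning, double loop, haversine."""
    R = 6371.0088
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))

    def dist(i, j):
        a = (np.sin((lat[j] - lat[i]) / 2) ** 2
             + np.cos(lat[i]) * np.cos(lat[j])
             * np.sin((lon[j] - lon[i]) / 2) ** 2)
        return 2 * R * np.arcsin(np.sqrt(a))

    kept: list[int] = []
    for i in range(len(lon)):
        if all(dist(i, j) >= radius_km for j in kept):
            kept.append(i)
    return kept


def newton_logistic(F, y, iterations: int = 100) -> np.ndarray:
    """Unpenalized logistic regression by Newton-Raphson (IRLS).

    Returns ``[intercept, coefficients...]``.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), F])
    w = np.zeros(X.shape[1])
    for _ in range(iterations):
        p = 1.0 / (1.0 + np.exp(-X @ w))
        weights = np.clip(p * (1 - p), 1e-10, None)
        H = X.T @ (weights[:, None] * X)
        step = np.linalg.solve(H, X.T @ (y - p))
        w = w + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return w


def univariate_probit_gibbs(x, y, iterations, burn_in, thin,
                            prior_sd: float = 10.0, seed: int = 0):
    """Albert-Chib Gibbs sampler for a univariate Bayesian probit.

    Model: y_i = 1[z_i > 0], z_i ~ N(a + b x_i, 1), independent
    N(0, prior_sd^2) priors on (a, b).  Truncated draws use
    scipy.stats.truncnorm and the coefficient draw uses an explicit
    covariance inverse — a different code path from the package sampler.

    Returns an array of retained (a, b) draws.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    W = np.column_stack([np.ones(n), x])
    precision = W.T @ W + np.eye(2) / prior_sd ** 2
    cov = np.linalg.inv(precision)
    cov_chol = np.linalg.cholesky(cov)
    coef = np.zeros(2)
    lower = np.where(y == 1, 0.0, -np.inf)
    upper = np.where(y == 1, np.inf, 0.0)
    draws = []
    for it in range(1, iterations + 1):
        mu = W @ coef
        z = truncnorm.rvs((lower - mu), (upper - mu), loc=mu, scale=1.0,
                          random_state=rng)
        mean = cov @ (W.T @ z)
        coef = mean + cov_chol @ rng.standard_normal(2)
        if it > burn_in and (it - burn_in) % thin == 0:
            draws.append(coef.copy())
    return np.asarray(draws)
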