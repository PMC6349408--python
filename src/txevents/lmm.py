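"""Maximum-likelihood fitting of the two small mixed models used here.

Both models are fitted by direct ML (not REML) so that likelihood-ratio
tests on fixed effects are valid:

* a Gaussian linear model with one random intercept per donor, fitted
  by profiling the fixed effects and residual variance out of the
  likelihood and optimising the single variance ratio numerically
  (Woodbury identities make each evaluation O(n)); and
* a random-effects-only decomposition ``y = mu + u_genotype +
  u_condition + u_interaction + e`` with independent components, fitted
  by bounded quasi-Newton optimisation of the exact Gaussian likelihood
  (Cholesky factorisation per evaluation).

Profiled/bounded optimisation keeps both fits well behaved when a
variance component sits on the zero boundary, which happens routinely
in null simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["RandomInterceptFit", "VarianceComponentsFit",
           "fit_random_intercept", "fit_variance_components"]


@dataclass
class RandomInterceptFit:
    loglik: float
    beta: np.ndarray
    sigma2_resid: float
    sigma2_group: float
    boundary: bool  # True when the group variance collapsed to zero


def _profile_loglik(lam: float, y, X, group_idx, group_sizes):
    """Profiled ML log-likelihood of y ~ X b + (1|group), V = I + lam ZZ'."""
    n, p = X.shape
    w = lam / (1.0 + lam * group_sizes)  # per-group Woodbury weight
    gsum_X = np.zeros((group_sizes.size, p))
    np.add.at(gsum_X, group_idx, X)
    gsum_y = np.bincount(group_idx, weights=y, minlength=group_sizes.size)
    XtVX = X.T @ X - (gsum_X * w[:, None]).T @ gsum_X
    XtVy = X.T @ y - (gsum_X * w[:, None]).T @ gsum_y
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    gsum_r = np.bincount(group_idx, weights=r, minlength=group_sizes.size)
    rss = r @ r - w @ gsum_r**2
    sigma2 = rss / n
    logdet = np.log1p(lam * group_sizes).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> RandomInterceptFit:
    """ML fit of ``y ~ X beta + (1 | groups)`` with Gaussian errors."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    _, group_idx = np.unique(groups, return_inverse=True)
    group_sizes = np.bincount(group_idx).astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")

    def nll_of_log_lambda(t: float) -> float:
        return -_profile_loglik(np.exp(t), y, X, group_idx, group_sizes)[0]

    # coarse grid on log lambda, then local refinement; lambda=0 boundary
    grid = np.linspace(-10.0, 8.0, 37)
    vals = [nll_of_log_lambda(t) for t in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    with np.errstate(invalid="ignore"):
        res = optimize.minimize_scalar(
            nll_of_log_lambda, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
    ll_lam, beta_lam, s2_lam = _profile_loglik(
        np.exp(res.x), y, X, group_idx, group_sizes
    )
    ll_zero, beta_zero, s2_zero = _profile_loglik(0.0, y, X, group_idx, group_sizes)
    if ll_zero >= ll_lam:
        return RandomInterceptFit(ll_zero, beta_zero, s2_zero, 0.0, boundary=True)
    lam = float(np.exp(res.x))
    return RandomInterceptFit(
        ll_lam, beta_lam, s2_lam, lam * s2_lam, boundary=False
    )


@dataclass
class VarianceComponentsFit:
    loglik: float
    mu: float
    components: dict[str, float]  # named variances, incl. "residual"


def _vc_nll(theta, y, ZZt_list):
    n = y.size
    sigma = theta[-1] * np.eye(n)
    for th, ZZt in zip(theta[:-1], ZZt_list):
        sigma += th * ZZt
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    ones = np.ones(n)
    si_y = np.linalg.solve(chol.T, np.linalg.solve(chol, y))
    si_1 = np.linalg.solve(chol.T, np.linalg.solve(chol, ones))
    mu = (ones @ si_y) / (ones @ si_1)
    r = y - mu
    si_r = np.linalg.solve(chol.T, np.linalg.solve(chol, r))
    return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ si_r)


def fit_variance_components(
    y: np.ndarray, factors: dict[str, np.ndarray]
) -> VarianceComponentsFit:
    """ML fit of ``y = mu + sum_k u_k[factor_k] + e`` (independent components).

    ``factors`` maps component name to an integer/str level vector of
    length n.  Component variances are constrained non-negative; the
    residual variance is kept strictly positive.  Several starting
    points guard against local optima.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    names = list(factors)
    ZZt_list = []
    for name in names:
        levels, idx = np.unique(np.asarray(factors[name]), return_inverse=True)
        Z = np.zeros((n, levels.size))
        Z[np.arange(n), idx] = 1.0
        ZZt_list.append(Z @ Z.T)

    vtot = max(float(np.var(y)), 1e-12)
    k = len(names) + 1
    starts = [
        np.full(k, vtot / k),
        np.concatenate([np.full(k - 1, vtot / (10 * k)), [vtot]]),
        np.concatenate([np.full(k - 1, vtot), [vtot / 10]]),
    ]
    bounds = [(0.0, None)] * (k - 1) + [(1e-10 * vtot, None)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _vc_nll, x0, args=(y, ZZt_list), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    # recover the profiled mean for reporting
    sigma = theta[-1] * np.eye(n)
    for th, ZZt in zip(theta[:-1], ZZt_list):
        sigma += th * ZZt
    ones = np.ones(n)
    si_y = np.linalg.solve(sigma, y)
    si_1 = np.linalg.solve(sigma, ones)
    mu = float((ones @ si_y) / (ones @ si_1))
    comps = {name: float(th) for name, th in zip(names, theta[:-1])}
    comps["residual"] = float(theta[-1])
    return VarianceComponentsFit(loglik=-float(best.fun), mu=mu, components=comps)
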