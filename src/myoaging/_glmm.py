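"""Laplace-approximation generalized linear mixed models for count data.

This is the numerical core shared by the compositional Poisson GLMM and the
per-gene negative-binomial aging model.  The approach follows the classical
``glmer``-style scheme:

1. for a given vector of random-effect standard deviations, the fixed
   effects ``beta`` and random-effect modes ``u`` jointly maximize the
   penalized log-likelihood via Fisher-scoring Newton steps;
2. the marginal likelihood of the variance components is approximated by
   Laplace's method using the curvature of the random-effect block at the
   mode;
3. the variance components (log standard deviations, which keeps them
   positive) maximize that approximate marginal likelihood with a
   quasi-Newton optimizer.

Posterior summaries for any linear contrast of coefficients come from the
inverse of the joint (beta, u) curvature at the optimum, i.e. the Gaussian
posterior the local true sign rate (LTSR) is evaluated under.

The negative binomial is parameterized by (mean, dispersion) with
``var = mu + mu^2 / dispersion``, so the Poisson is the infinite-dispersion
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

__all__ = [
    "REGroup",
    "GLMMFit",
    "indicator_matrix",
    "interaction_labels",
    "fit_glmm",
    "poisson_loglik",
    "negbin_loglik",
]

_LOG_SD_MIN = np.log(1e-4)
_LOG_SD_MAX = np.log(10.0)


@dataclass
class REGroup:
    """One random-effect grouping term.

    ``Z`` is the n x q design block: indicator columns for random
    intercepts, or the slope covariate placed in the level's column for
    random slopes.  ``levels`` names the q columns.
    """

    name: str
    Z: sp.csr_matrix
    levels: list[str]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class GLMMFit:
    """Result of a Laplace GLMM fit."""

    beta: np.ndarray
    u: np.ndarray  # concatenated random coefficients, group order
    log_sd: np.ndarray  # per free group, log scale
    group_names: list[str]
    group_slices: dict[str, slice]  # into u
    group_levels: dict[str, list[str]]
    sd: dict[str, float]
    loglik: float  # Laplace-approximated marginal log-likelihood
    post_cov: np.ndarray  # joint (beta, u) posterior covariance
    converged: bool
    n_fixed: int
    message: str = ""
    extra: dict = field(default_factory=dict)

    def coef_index(self, group: str, level: str) -> int:
        """Index of a random coefficient in the joint (beta, u) vector."""
        sl = self.group_slices[group]
        return self.n_fixed + sl.start + self.group_levels[group].index(level)

    def contrast(self, a: np.ndarray) -> tuple[float, float]:
        """Posterior mean and sd of the linear contrast ``a @ (beta, u)``."""
        theta = np.concatenate([self.beta, self.u])
        mean = float(a @ theta)
        var = float(a @ self.post_cov @ a)
        return mean, float(np.sqrt(max(var, 0.0)))


def indicator_matrix(labels: np.ndarray, values: np.ndarray | None = None):
    """Sparse n x q block: one column per level; entries 1 or a slope value."""
    labels = np.asarray(labels)
    levels = sorted(pd_unique(labels))
    col = {lv: j for j, lv in enumerate(levels)}
    rows = np.arange(labels.size)
    cols = np.array([col[lv] for lv in labels])
    data = np.ones(labels.size) if values is None else np.asarray(values, float)
    Z = sp.csr_matrix((data, (rows, cols)), shape=(labels.size, len(levels)))
    return Z, [str(lv) for lv in levels]


def pd_unique(labels: np.ndarray) -> list:
    return list(dict.fromkeys(labels.tolist()))


def interaction_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.char.add(np.char.add(np.asarray(a, str), "::"), np.asarray(b, str))


# ---------------------------------------------------------------------------
# family log-likelihoods and Fisher weights


def poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(eta)
    return float(np.sum(y * eta - mu - gammaln(y + 1.0)))


def negbin_loglik(y: np.ndarray, eta: np.ndarray, alpha: float) -> float:
    mu = np.exp(eta)
    return float(
        np.sum(
            gammaln(y + alpha)
            - gammaln(alpha)
            - gammaln(y + 1.0)
            + alpha * (np.log(alpha) - np.log(alpha + mu))
            + y * (eta - np.log(alpha + mu))
        )
    )


def _score_weights(y, eta, family, alpha):
    """Working score dl/deta and Fisher weights -E[d2l/deta2]."""
    mu = np.exp(eta)
    if family == "poisson":
        return y - mu, mu
    s = alpha / (alpha + mu)
    return (y - mu) * s, mu * s


def _make_loglik(y, family, alpha):
    """Log-likelihood as a function of eta with data constants hoisted."""
    if family == "poisson":
        const = -float(np.sum(gammaln(y + 1.0)))

        def ll(eta):
            return const + float(np.sum(y * eta - np.exp(eta)))

        return ll
    const = float(
        np.sum(gammaln(y + alpha) - gammaln(alpha) - gammaln(y + 1.0))
        + y.size * alpha * np.log(alpha)
    )

    def ll(eta):
        mu = np.exp(eta)
        return const + float(np.sum(y * eta - (alpha + y) * np.log(alpha + mu)))

    return ll


# ---------------------------------------------------------------------------
# inner penalized Newton


def _penalized_newton(
    y, M, n_fixed, prior_prec, offset, theta0, family, alpha, tol=1e-10, max_iter=60,
    loglik_fn=None,
):
    """Jointly maximize loglik(eta) - 0.5 * u' P u over theta = (beta, u).

    ``prior_prec`` is the diagonal precision for the whole theta vector
    (zeros over the fixed-effect block).  Uses Fisher scoring with step
    halving; returns (theta, penalized loglik, A) where A is the curvature
    M'WM + diag(P) at the optimum.
    """
    theta = theta0.copy()
    dense = not sp.issparse(M)
    eta = offset + M @ theta

    def curvature(w):
        if dense:
            A = (M * w[:, None]).T @ M
        else:
            A = (M.T @ sp.diags(w) @ M).toarray()
        A[np.diag_indices_from(A)] += prior_prec
        return A

    if loglik_fn is None:
        loglik_fn = _make_loglik(y, family, alpha)

    def pen_ll(th, et):
        return loglik_fn(et) - 0.5 * float(prior_prec @ (th * th))

    f = pen_ll(theta, eta)
    A = None
    for _ in range(max_iter):
        g_eta, w = _score_weights(y, eta, family, alpha)
        grad = M.T @ g_eta - prior_prec * theta
        A = curvature(w)
        try:
            c, low = cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            A[np.diag_indices_from(A)] += 1e-8
            c, low = cho_factor(A, lower=True, check_finite=False)
        step = cho_solve((c, low), grad, check_finite=False)
        if not np.all(np.isfinite(step)):
            break
        # step halving for stability at extreme starts
        t = 1.0
        for _ in range(30):
            theta_new = theta + t * step
            eta_new = offset + M @ theta_new
            f_new = pen_ll(theta_new, eta_new)
            if np.isfinite(f_new) and f_new >= f - 1e-12:
                break
            t *= 0.5
        gain = f_new - f
        theta, eta, f = theta_new, eta_new, f_new
        if np.linalg.norm(grad) < tol or (0 <= gain < tol):
            break
    # refresh curvature at optimum
    g_eta, w = _score_weights(y, eta, family, alpha)
    A = curvature(w)
    grad = M.T @ g_eta - prior_prec * theta
    return theta, f, A, float(np.linalg.norm(grad))


def _logdet_chol(A: np.ndarray) -> float:
    c, _ = cho_factor(A, lower=True, check_finite=False)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


# ---------------------------------------------------------------------------
# public fit


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: list[REGroup],
    family: str = "poisson",
    dispersion: float | None = None,
    offset: np.ndarray | None = None,
    init_sd: float = 0.1,
    gtol: float = 1e-8,
    max_outer: int = 200,
    fixed_sd: dict[str, float] | None = None,
) -> GLMMFit:
    """Fit a Poisson or negative-binomial GLMM by Laplace approximation.

    Parameters
    ----------
    y
        Non-negative integer response.
    X
        Fixed-effect design (n x p), fitted without shrinkage.
    groups
        Random-effect terms.  A group whose ``Z`` has zero columns is
        ignored.  Pass ``groups=[]`` for a plain GLM (the zero-variance
        limit, in which the fit reduces to the ordinary MLE).
    family
        "poisson" or "negbin" (requires ``dispersion``).
    dispersion
        NB dispersion ``alpha`` with var = mu + mu^2/alpha; ignored for
        Poisson.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    if family == "negbin":
        if dispersion is None or dispersion <= 0:
            raise ValueError("negbin family requires dispersion > 0")
        alpha = float(dispersion)
    else:
        alpha = None
    groups = [g for g in groups if g.q > 0]
    ll_fn = _make_loglik(y, family, alpha)

    q_total = sum(g.q for g in groups)
    if groups:
        M = sp.hstack([sp.csr_matrix(X)] + [g.Z for g in groups], format="csr")
        if p + q_total <= 64:
            # dense BLAS beats sparse overhead for small coefficient counts
            M = np.asarray(M.todense())
    else:
        M = X
    slices: dict[str, slice] = {}
    start = 0
    for g in groups:
        slices[g.name] = slice(start, start + g.q)
        start += g.q
    group_idx = np.concatenate(
        [np.full(g.q, i) for i, g in enumerate(groups)]
    ) if groups else np.zeros(0, int)

    state = {"theta": np.zeros(p + q_total)}
    fixed_sd = fixed_sd or {}
    free_ix = [i for i, g in enumerate(groups) if g.name not in fixed_sd]
    full_template = np.zeros(len(groups))
    for i, g in enumerate(groups):
        if g.name in fixed_sd:
            if fixed_sd[g.name] <= 0:
                raise ValueError("fixed_sd values must be > 0")
            full_template[i] = np.log(fixed_sd[g.name])

    def full_log_sd(free: np.ndarray) -> np.ndarray:
        full = full_template.copy()
        full[free_ix] = free
        return full

    def prior_precision(log_sd: np.ndarray) -> np.ndarray:
        prec = np.zeros(p + q_total)
        if q_total:
            prec[p:] = np.exp(-2.0 * log_sd[group_idx])
        return prec

    def neg_marginal(free: np.ndarray) -> float:
        log_sd = full_log_sd(free)
        prec = prior_precision(log_sd)
        theta, pen_ll, A, _ = _penalized_newton(
            y, M, p, prec, offset, state["theta"], family, alpha, loglik_fn=ll_fn
        )
        state["theta"] = theta
        # Laplace: pen_ll - 0.5 log|D| - 0.5 log|H_uu|  (2*pi factors cancel)
        logdet_D = float(np.sum(2.0 * log_sd[group_idx])) if q_total else 0.0
        H_uu = A[p:, p:]
        logdet_H = _logdet_chol(H_uu) if q_total else 0.0
        return -(pen_ll - 0.5 * logdet_D - 0.5 * logdet_H)

    converged = True
    message = "ok"
    if q_total == 0:
        log_sd_opt = np.zeros(0)
        prec = prior_precision(log_sd_opt)
        theta, pen_ll, A, gnorm = _penalized_newton(
            y, M, p, prec, offset, state["theta"], family, alpha, tol=1e-12,
            loglik_fn=ll_fn,
        )
        state["theta"] = theta
        loglik = pen_ll
        converged = gnorm < max(gtol, 1e-6)
    elif len(free_ix) == 0:
        loglik = -neg_marginal(np.zeros(0))
        log_sd_opt = full_template.copy()
    elif len(free_ix) == 1:
        res = scipy.optimize.minimize_scalar(
            lambda s: neg_marginal(np.array([s])),
            bounds=(_LOG_SD_MIN, _LOG_SD_MAX),
            method="bounded",
            options={"xatol": 1e-4, "maxiter": max_outer},
        )
        log_sd_opt = full_log_sd(np.array([res.x]))
        loglik = -float(res.fun)
        converged = bool(res.success)
        message = str(res.message)
    else:
        x0 = np.full(len(free_ix), np.log(init_sd))
        res = scipy.optimize.minimize(
            neg_marginal,
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_SD_MIN, _LOG_SD_MAX)] * len(free_ix),
            options={"maxiter": max_outer, "ftol": 1e-10, "gtol": gtol},
        )
        log_sd_opt = full_log_sd(res.x)
        loglik = -float(res.fun)
        converged = bool(res.success) or res.status == 1
        message = str(res.message)

    if q_total > 0:
        # final inner solve at the optimum for posterior summaries
        prec = prior_precision(log_sd_opt)
        theta, _, A, _ = _penalized_newton(
            y, M, p, prec, offset, state["theta"], family, alpha, tol=1e-12,
            loglik_fn=ll_fn,
        )
        state["theta"] = theta

    theta = state["theta"]
    post_cov = np.linalg.inv(A)

    return GLMMFit(
        beta=theta[:p].copy(),
        u=theta[p:].copy(),
        log_sd=log_sd_opt,
        group_names=[g.name for g in groups],
        group_slices=slices,
        group_levels={g.name: g.levels for g in groups},
        sd={g.name: float(np.exp(s)) for g, s in zip(groups, log_sd_opt)},
        loglik=float(loglik),
        post_cov=post_cov,
        converged=converged,
        n_fixed=p,
        message=message,
    )
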