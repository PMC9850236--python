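"""Weighted conditional logistic regression.

Each stratum holds one case day and its referent days; the conditional
likelihood is the multinomial-logit probability of the case day within
its stratum, weighted by the number of deaths the stratum represents:

    l(beta) = sum_s  w_s * [ eta_case(s) - log sum_{d in s} exp(eta_d) ]

Stratum intercepts cancel, so covariates constant within every stratum
are unidentifiable; such columns are detected, dropped and reported.
Maximisation is Newton-Raphson with step-halving; the covariance is the
inverse observed information at the optimum (a robust sandwich variant
is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AliasingError, ConvergenceError

__all__ = ["FitResult", "conditional_logistic_fit"]

ALIAS_TOL = 1e-12


@dataclass
class FitResult:
    """Coefficients and covariance from a conditional-logistic fit."""

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_strata: int
    n_weighted_cases: float
    converged: bool
    n_iter: int
    colnames: list = field(default_factory=list)
    dropped: list = field(default_factory=list)
    score_norm: float = np.nan

    def coef(self, names):
        """Coefficient subvector for the given column names (zero for
        dropped columns)."""
        idx = {c: i for i, c in enumerate(self.colnames)}
        out = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm in idx:
                out[i] = self.beta[idx[nm]]
        return out

    def vcov_block(self, names_a, names_b=None):
        """Covariance block between two coefficient groups (zeros for
        dropped columns)."""
        if names_b is None:
            names_b = names_a
        idx = {c: i for i, c in enumerate(self.colnames)}
        out = np.zeros((len(names_a), len(names_b)))
        for i, na in enumerate(names_a):
            if na not in idx:
                continue
            for j, nb in enumerate(names_b):
                if nb in idx:
                    out[i, j] = self.vcov[idx[na], idx[nb]]
        return out


def _stratum_slices(stratum_ids):
    """Row slices per stratum; requires rows sorted by stratum id."""
    ids = np.asarray(stratum_ids)
    if np.any(ids[1:] < ids[:-1]):
        order = np.argsort(ids, kind="stable")
    else:
        order = np.arange(len(ids))
    sorted_ids = ids[order]
    starts = np.flatnonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])
    return order, starts


def _loglik_parts(X, y, w_row, starts, beta):
    """Log-likelihood, per-row case probabilities, and per-stratum
    weighted mean covariates."""
    eta = X @ beta
    # segmented logsumexp
    n_strata = len(starts)
    ends = np.r_[starts[1:], len(eta)]
    m = np.maximum.reduceat(eta, starts)
    rep = np.repeat(np.arange(n_strata), ends - starts)
    ex = np.exp(eta - m[rep])
    denom = np.add.reduceat(ex, starts)
    p = ex / denom[rep]
    lse = m + np.log(denom)
    eta_case = np.add.reduceat(eta * y, starts)
    w_s = np.add.reduceat(w_row * y, starts) / np.maximum(np.add.reduceat(y, starts), 1)
    ll = float(np.sum(w_s * (eta_case - lse)))
    return ll, p, rep, w_s


def conditional_logistic_fit(design, options=None) -> FitResult:
    """Maximise the weighted conditional-logistic likelihood.

    Parameters
    ----------
    design : object with attributes ``X`` (n, p), ``y`` (n,), ``stratum_ids``
        (n,), ``weights`` (n,) row weights equal within each stratum, and
        optionally ``colnames``.
    options : dict, optional
        ``tol`` (score max-norm, default 1e-8), ``max_iter`` (50),
        ``robust`` (False: observed-information covariance).
    """
    opts = {"tol": 1e-8, "max_iter": 50, "robust": False}
    if options:
        opts.update(options)

    X = np.asarray(design.X, dtype=float)
    y = np.asarray(design.y, dtype=float)
    w_row = np.asarray(design.weights, dtype=float)
    colnames = list(getattr(design, "colnames", None) or
                    [f"x{i}" for i in range(X.shape[1])])

    order, starts = _stratum_slices(design.stratum_ids)
    X, y, w_row = X[order], y[order], w_row[order]
    n_strata = len(starts)
    if n_strata < 1:
        raise AliasingError("no strata in design")
    ends = np.r_[starts[1:], len(y)]
    rep = np.repeat(np.arange(n_strata), ends - starts)

    # aliased columns: no within-stratum variation in any stratum
    counts = ends - starts
    means = np.add.reduceat(X, starts, axis=0) / counts[:, None]
    centered = X - means[rep]
    within_var = np.add.reduceat(centered**2, starts, axis=0) / counts[:, None]
    aliased = within_var.max(axis=0) < ALIAS_TOL
    dropped = [c for c, a in zip(colnames, aliased) if a]
    keep = ~aliased
    if not np.any(keep):
        raise AliasingError(
            "every covariate is constant within every stratum", columns=dropped)
    Xk = X[:, keep]
    kept_names = [c for c, a in zip(colnames, aliased) if not a]
    p_dim = Xk.shape[1]

    # standardise columns for optimisation (scale only: levels cancel
    # within strata anyway); coefficients are mapped back at the end
    scales = Xk.std(axis=0)
    scales[scales < 1e-300] = 1.0
    Xk = Xk / scales
    # score tolerance per weighted case: the likelihood and its gradient
    # grow linearly with the total death count
    tol = opts["tol"] * max(1.0, float(np.sum(w_row * y)))

    beta = np.zeros(p_dim)
    ll, p, rep, w_s = _loglik_parts(Xk, y, w_row, starts, beta)
    n_iter = 0
    converged = False
    grad_norm = np.inf
    for n_iter in range(1, opts["max_iter"] + 1):
        wp = w_s[rep] * p
        xbar = np.add.reduceat(wp[:, None] * Xk, starts, axis=0) / w_s[:, None]
        grad = Xk.T @ (w_row * y) - (w_s[:, None] * xbar).sum(axis=0)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            converged = True
            break
        info = (Xk * wp[:, None]).T @ Xk - (xbar * w_s[:, None]).T @ xbar
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise AliasingError(
                "singular information matrix; collinear columns among "
                f"{kept_names}", columns=kept_names)
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            ll_new, p_new, _, _ = _loglik_parts(Xk, y, w_row, starts, beta + scale * step)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll, p = ll_new, p_new
    else:
        raise ConvergenceError(
            f"no convergence after {opts['max_iter']} iterations "
            f"(score max-norm {grad_norm:.3e})",
            beta=beta, grad_norm=grad_norm, n_iter=n_iter)

    wp = w_s[rep] * p
    xbar = np.add.reduceat(wp[:, None] * Xk, starts, axis=0) / w_s[:, None]
    info = (Xk * wp[:, None]).T @ Xk - (xbar * w_s[:, None]).T @ xbar
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise AliasingError("singular information at the optimum", columns=kept_names)
    if opts["robust"]:
        resid = (w_row * (y - p))[:, None] * Xk
        score_s = np.add.reduceat(resid, starts, axis=0)
        meat = score_s.T @ score_s
        vcov = vcov @ meat @ vcov
    vcov = (vcov + vcov.T) / 2.0

    # map back to the original column scaling
    beta = beta / scales
    vcov = vcov / np.outer(scales, scales)

    return FitResult(
        beta=beta, vcov=vcov, loglik=ll, n_strata=n_strata,
        n_weighted_cases=float(np.sum(w_s)), converged=converged,
        n_iter=n_iter, colnames=kept_names, dropped=dropped,
        score_norm=grad_norm)
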