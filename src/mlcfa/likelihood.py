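"""Normal-theory likelihoods for balanced two-level data.

For a balanced design the stacked nP-dimensional per-cluster covariance
``I_n (x) Sigma_W + J_n (x) Sigma_B`` diagonalizes into (n - 1) copies of
``Sigma_W`` and one copy of ``Sigma_n = Sigma_W + n Sigma_B``, giving

    -2 ln L = N P ln 2pi
              + (N - G) [ ln|Sigma_W| + tr(Sigma_W^-1 S_PW) ]
              + G       [ ln|Sigma_n| + tr(Sigma_n^-1 S_n(mu)) ]

with ``S_PW`` the pooled within-cluster covariance (ML divisor N - G) and
``S_n(mu)`` the ML scatter of the scaled cluster means about the implied
means.  This equals the stacked multivariate-normal log-likelihood exactly;
the equality is enforced by tests against a brute-force oracle.  The
one-level model uses the standard single-group ML discrepancy against the
total covariance and mean.

Singular or non-positive-definite implied matrices yield ``+inf`` — the
condition is signaled, never clipped.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .moments import ImpliedCovariances, MomentSummary
from .specs import ModelSpec, ParameterVector, get_spec

__all__ = ["neg2loglik", "neg2loglik_implied", "neg2loglik_and_grad",
           "cluster_neg2loglik", "cluster_scores",
           "saturated_neg2loglik", "baseline_neg2loglik"]

_LOG2PI = np.log(2.0 * np.pi)


def _chol(mat):
    """Cholesky factor or None for a non-PD matrix."""
    try:
        c, low = cho_factor(mat, lower=True, check_finite=False)
    except (LinAlgError, ValueError):
        return None
    if not np.all(np.isfinite(c)):
        return None
    return c, low


def _logdet(cf):
    return 2.0 * np.sum(np.log(np.diag(cf[0])))


def neg2loglik_implied(imp: ImpliedCovariances, mom: MomentSummary) -> float:
    """-2 ln L of implied matrices given balanced-design sufficient statistics."""
    P, N, G, n = mom.n_indicators, mom.N, mom.G, mom.n
    d = mom.grand_mean - imp.mu
    if imp.is_onelevel:
        cf = _chol(imp.sigma_total)
        if cf is None:
            return np.inf
        S = mom.total_ml + np.outer(d, d)
        return N * (P * _LOG2PI + _logdet(cf)
                    + np.trace(cho_solve(cf, S, check_finite=False)))
    sigma_n = imp.sigma_within + n * imp.sigma_between
    cf_w = _chol(imp.sigma_within)
    cf_n = _chol(sigma_n)
    if cf_w is None or cf_n is None:
        return np.inf
    S_n = n * (mom.between_ml + np.outer(d, d))
    return (N * P * _LOG2PI
            + (N - G) * (_logdet(cf_w)
                         + np.trace(cho_solve(cf_w, mom.pooled_within,
                                              check_finite=False)))
            + G * (_logdet(cf_n)
                   + np.trace(cho_solve(cf_n, S_n, check_finite=False))))


def neg2loglik(spec, params, moments: MomentSummary) -> float:
    """-2 ln L of a model specification at a parameter vector."""
    spec = get_spec(spec)
    values = params.values if isinstance(params, ParameterVector) else params
    return neg2loglik_implied(spec.implied(values), moments)


def neg2loglik_and_grad(spec, values, mom: MomentSummary):
    """-2 ln L and its analytic gradient over the free parameters.

    The gradient chains d(-2lnL)/dSigma (matrix-calculus identities for the
    log-determinant and trace terms) through the spec's structure
    derivatives.  Returns ``(inf, None)`` at a non-PD point.
    """
    spec = get_spec(spec)
    values = np.asarray(getattr(values, "values", values), dtype=float)
    imp = spec.implied(values)
    P, N, G, n = mom.n_indicators, mom.N, mom.G, mom.n
    d = mom.grand_mean - imp.mu

    if imp.is_onelevel:
        cf = _chol(imp.sigma_total)
        if cf is None:
            return np.inf, None
        inv = cho_solve(cf, np.eye(P), check_finite=False)
        S = mom.total_ml + np.outer(d, d)
        f = N * (P * _LOG2PI + _logdet(cf) + np.sum(inv * S))
        dmu, dSt = spec.implied_grad(values)
        K = inv - inv @ S @ inv
        grad = N * (np.einsum("jpq,pq->j", dSt, K)
                    - 2.0 * dmu @ (inv @ d))
        return f, grad

    sigma_n = imp.sigma_within + n * imp.sigma_between
    cf_w = _chol(imp.sigma_within)
    cf_n = _chol(sigma_n)
    if cf_w is None or cf_n is None:
        return np.inf, None
    inv_w = cho_solve(cf_w, np.eye(P), check_finite=False)
    inv_n = cho_solve(cf_n, np.eye(P), check_finite=False)
    S_n = n * (mom.between_ml + np.outer(d, d))
    f = (N * P * _LOG2PI
         + (N - G) * (_logdet(cf_w) + np.sum(inv_w * mom.pooled_within))
         + G * (_logdet(cf_n) + np.sum(inv_n * S_n)))
    dmu, dSw, dSb = spec.implied_grad(values)
    K_w = inv_w - inv_w @ mom.pooled_within @ inv_w
    K_n = inv_n - inv_n @ S_n @ inv_n
    dSn = dSw + n * dSb
    grad = ((N - G) * np.einsum("jpq,pq->j", dSw, K_w)
            + G * np.einsum("jpq,pq->j", dSn, K_n)
            - 2.0 * n * G * dmu @ (inv_n @ d))
    return f, grad


def cluster_neg2loglik(spec: ModelSpec, values: np.ndarray,
                       mom: MomentSummary) -> np.ndarray:
    """Per-cluster contributions to -2 ln L (length G, sums to the total).

    Clusters are the independent sampling units for every specification,
    including the one-level model; these contributions are the basis of the
    cluster-robust sandwich estimator.
    """
    spec = get_spec(spec)
    imp = spec.implied(np.asarray(values, dtype=float))
    P, n, G = mom.n_indicators, mom.n, mom.G
    dev = mom.cluster_means - imp.mu  # G x P
    if imp.is_onelevel:
        cf = _chol(imp.sigma_total)
        if cf is None:
            return np.full(G, np.inf)
        inv = cho_solve(cf, np.eye(P), check_finite=False)
        tr_w = np.einsum("pq,gqp->g", inv, mom.within_scatter)
        quad = n * np.einsum("gp,pq,gq->g", dev, inv, dev)
        return n * (P * _LOG2PI + _logdet(cf)) + tr_w + quad
    sigma_n = imp.sigma_within + n * imp.sigma_between
    cf_w = _chol(imp.sigma_within)
    cf_n = _chol(sigma_n)
    if cf_w is None or cf_n is None:
        return np.full(G, np.inf)
    inv_w = cho_solve(cf_w, np.eye(P), check_finite=False)
    inv_n = cho_solve(cf_n, np.eye(P), check_finite=False)
    tr_w = np.einsum("pq,gqp->g", inv_w, mom.within_scatter)
    quad = n * np.einsum("gp,pq,gq->g", dev, inv_n, dev)
    return (n * P * _LOG2PI + (n - 1) * _logdet(cf_w) + _logdet(cf_n)
            + tr_w + quad)


def cluster_scores(spec, values, mom: MomentSummary) -> np.ndarray | None:
    """G x k matrix of per-cluster gradients of the -2 ln L contributions.

    Rows sum to the total gradient; at the ML solution the column sums
    vanish, and the matrix of outer products is the "meat" of the
    cluster-robust sandwich.  Returns ``None`` at a non-PD point.
    """
    spec = get_spec(spec)
    values = np.asarray(getattr(values, "values", values), dtype=float)
    imp = spec.implied(values)
    P, n = mom.n_indicators, mom.n
    dev = mom.cluster_means - imp.mu  # G x P

    if imp.is_onelevel:
        cf = _chol(imp.sigma_total)
        if cf is None:
            return None
        inv = cho_solve(cf, np.eye(P), check_finite=False)
        dmu, dSt = spec.implied_grad(values)
        C = mom.within_scatter + n * np.einsum("gp,gq->gpq", dev, dev)
        K = n * inv[None] - np.einsum("pq,gqr,rs->gps", inv, C, inv)
        q = dev @ inv  # G x P
        return (np.einsum("gpq,jpq->gj", K, dSt)
                - 2.0 * n * q @ dmu.T)

    sigma_n = imp.sigma_within + n * imp.sigma_between
    cf_w = _chol(imp.sigma_within)
    cf_n = _chol(sigma_n)
    if cf_w is None or cf_n is None:
        return None
    inv_w = cho_solve(cf_w, np.eye(P), check_finite=False)
    inv_n = cho_solve(cf_n, np.eye(P), check_finite=False)
    dmu, dSw, dSb = spec.implied_grad(values)
    dSn = dSw + n * dSb
    K_w = ((n - 1) * inv_w[None]
           - np.einsum("pq,gqr,rs->gps", inv_w, mom.within_scatter, inv_w))
    q = dev @ inv_n  # G x P
    K_n = inv_n[None] - n * np.einsum("gp,gq->gpq", q, q)
    return (np.einsum("gpq,jpq->gj", K_w, dSw)
            + np.einsum("gpq,jpq->gj", K_n, dSn)
            - 2.0 * n * q @ dmu.T)


def saturated_neg2loglik(mom: MomentSummary, onelevel: bool) -> float:
    """-2 ln L of the saturated reference model (closed form on balanced data).

    Two-level specs are referenced against the model with both level
    covariance matrices and the means saturated; the one-level spec against
    the single-group saturated model.
    """
    spec = get_spec("_SAT1" if onelevel else "_SAT2",
                    labels=tuple(f"v{i}" for i in range(mom.n_indicators)))
    return neg2loglik_implied(spec.implied(spec.start_values(mom)), mom)


def baseline_neg2loglik(mom: MomentSummary, onelevel: bool) -> float:
    """-2 ln L of the independence (diagonal-covariance) baseline model."""
    spec = get_spec("_BASE1" if onelevel else "_BASE2",
                    labels=tuple(f"v{i}" for i in range(mom.n_indicators)))
    return neg2loglik_implied(spec.implied(spec.start_values(mom)), mom)
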