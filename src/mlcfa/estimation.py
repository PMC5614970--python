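"""Maximum-likelihood fitting with cluster-robust (sandwich) inference.

The optimizer is quasi-Newton (L-BFGS-B) with analytic gradients on the
unconstrained raw parameter vector; steps into non-positive-definite implied
matrices are rejected through a large finite penalty rather than by
reparameterizing variances to logs, so estimates and standard errors are
reported on the natural scale and Heywood cases (negative variance
estimates) survive as-is with an inadmissibility flag.

Robust covariance of the estimates is the sandwich A^-1 B A^-1 with A the
observed information of the total -2 ln L (central differences of the
analytic gradient) and B the sum over clusters of outer products of
per-cluster score contributions; clusters are the independent units for
every specification, including the one-level model.  The robust
("mean-adjusted") chi-square divides the likelihood-ratio statistic against
the saturated model by the scaling factor

    c = [tr(A_sat^-1 B_sat) - tr(A_model^-1 B_model)] / df,

which tends to 1 under multivariate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .likelihood import (cluster_scores, neg2loglik, neg2loglik_and_grad,
                         neg2loglik_implied)
from .moments import MomentSummary, compute_moments
from .results import MultilevelFactorResults
from .sampling import TwoLevelSample
from .specs import ModelSpec, get_spec

__all__ = ["fit", "sandwich_covariance", "scaled_chisq", "reference_info",
           "ReferenceInfo"]

_PENALTY = 1e10


def _hessian_from_grad(spec: ModelSpec, x: np.ndarray, mom: MomentSummary,
                       rel_step: float = 1e-5) -> np.ndarray:
    """Hessian of the total -2 ln L: central differences of the gradient."""
    k = x.size
    H = np.full((k, k), np.nan)
    for i in range(k):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = neg2loglik_and_grad(spec, xp, mom)
        _, gm = neg2loglik_and_grad(spec, xm, mom)
        if gp is None or gm is None:
            return H
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2.0


def _info_at(spec: ModelSpec, values: np.ndarray, mom: MomentSummary):
    """Observed information pieces at a parameter point.

    Returns (H, D, trace): the Hessian of the total -2 ln L, the sum of
    per-cluster score outer products on the same scale, and
    trace = tr(A^-1 B) = 0.5 tr(H^-1 D) on the log-likelihood scale.
    """
    values = np.asarray(values, dtype=float)
    H = _hessian_from_grad(spec, values, mom)
    scores = cluster_scores(spec, values, mom)
    D = (scores.T @ scores if scores is not None
         else np.full((values.size, values.size), np.nan))
    trace = np.nan
    if np.all(np.isfinite(H)) and np.all(np.isfinite(D)):
        try:
            trace = 0.5 * np.trace(np.linalg.solve(H, D))
        except np.linalg.LinAlgError:
            pass
    return H, D, trace


@dataclass(frozen=True)
class ReferenceInfo:
    """Saturated-model quantities shared by every fit on the same data."""

    neg2loglik: float
    trace_hinv_d: float
    onelevel: bool


def reference_info(mom: MomentSummary, onelevel: bool) -> ReferenceInfo:
    """Saturated-model -2 ln L and robust trace term (closed-form solution)."""
    spec = get_spec("_SAT1" if onelevel else "_SAT2",
                    labels=tuple(f"v{i}" for i in range(mom.n_indicators)))
    sol = spec.start_values(mom)
    value = neg2loglik_implied(spec.implied(sol), mom)
    _, _, trace = _info_at(spec, sol, mom)
    return ReferenceInfo(value, trace, onelevel)


# ---------------------------------------------------------------------------
# public operations

def sandwich_covariance(spec, params, data) -> np.ndarray:
    """Cluster-robust covariance A^-1 B A^-1 of the free-parameter estimates.

    ``params`` should be the ML solution; ``data`` is a
    :class:`TwoLevelSample` or precomputed :class:`MomentSummary`.
    """
    mom = compute_moments(data) if isinstance(data, TwoLevelSample) else data
    spec = get_spec(spec)
    values = np.asarray(getattr(params, "values", params), dtype=float)
    H, D, _ = _info_at(spec, values, mom)
    Hinv = np.linalg.inv(H)
    return Hinv @ D @ Hinv


def scaled_chisq(fit_result, reference: ReferenceInfo | None = None):
    """Robust-scaled likelihood-ratio statistic and its scaling factor.

    The statistic equals (-2 ln L_model + 2 ln L_saturated) / c with the
    mean-adjusted correction factor c; under multivariate normal data c
    tends to 1.  Propagates non-convergence as NaN.
    """
    if not fit_result.converged:
        return np.nan, np.nan
    if reference is None:
        reference = fit_result._reference
    df = fit_result.chisq_df
    t_raw = max(fit_result.neg2loglik - reference.neg2loglik, 0.0)
    if df == 0:
        return 0.0, 1.0
    c = (reference.trace_hinv_d - fit_result._trace_hinv_d) / df
    if not np.isfinite(c) or c <= 0:
        return np.nan, c
    return t_raw / c, c


def fit(spec, data, labels=None, start=None, gtol: float = 1e-5,
        maxiter: int = 2000, reference: ReferenceInfo | None = None,
        ) -> MultilevelFactorResults:
    """Fit one model specification to a balanced two-level sample by ML.

    Parameters
    ----------
    spec : str or ModelSpec
        One of ``2MLR``, ``1MLR``, ``2MaxB``, ``2MaxW``, ``2Miss``.
    data : TwoLevelSample or MomentSummary
        The sample (or its sufficient statistics).
    start : array, optional
        Starting values; defaults to the deterministic scheme of the spec.
    gtol : float
        Convergence requires max |gradient| of -2lnL/N below this.
    reference : ReferenceInfo, optional
        Pre-computed saturated-model quantities (reused when several specs
        are fitted to the same data).

    Routine non-convergence never raises: the result carries
    ``converged=False`` with diagnostics.
    """
    if isinstance(data, TwoLevelSample):
        mom = compute_moments(data)
        if labels is None:
            labels = data.labels
    else:
        mom = data
    spec = get_spec(spec) if labels is None else get_spec(spec, tuple(labels))
    N = mom.N

    def objective(x):
        f, g = neg2loglik_and_grad(spec, x, mom)
        if g is None:
            return _PENALTY, np.zeros_like(x)
        return f / N, g / N

    x0 = np.asarray(start, dtype=float) if start is not None \
        else spec.start_values(mom)

    opt = minimize(objective, x0, method="L-BFGS-B", jac=True,
                   options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                            "ftol": 1e-13, "gtol": 1e-7})
    x = opt.x
    f_val, grad = objective(x)
    if np.max(np.abs(grad)) > gtol:  # one polish pass from the current point
        opt = minimize(objective, x, method="L-BFGS-B", jac=True,
                       options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                                "ftol": 1e-15, "gtol": 1e-9})
        x = opt.x
        f_val, grad = objective(x)

    converged = bool(np.isfinite(f_val) and f_val < _PENALTY
                     and np.max(np.abs(grad)) <= gtol)
    neg2 = f_val * N

    H, D, trace = _info_at(spec, x, mom)
    se = np.full(spec.n_params, np.nan)
    cov = np.full((spec.n_params, spec.n_params), np.nan)
    admissible = False
    if np.all(np.isfinite(H)) and np.all(np.isfinite(D)):
        try:
            np.linalg.cholesky((H + H.T) / 2)  # observed information PD?
            Hinv = np.linalg.inv(H)
            cov = Hinv @ D @ Hinv
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = np.sqrt(diag)
                admissible = True
        except np.linalg.LinAlgError:
            pass
    if not admissible:
        converged = False  # non-PD information: classified non-converged

    if reference is None or reference.onelevel != spec.onelevel:
        reference = reference_info(mom, spec.onelevel)

    result = MultilevelFactorResults(
        spec=spec,
        params=spec.parameter_vector(x),
        bse=se,
        cov_params=cov,
        neg2loglik=neg2,
        chisq_df=spec.df,
        converged=converged,
        admissible=admissible,
        moments=mom,
        optimizer_message=str(opt.message),
        n_iter=int(opt.nit),
        max_abs_grad=float(np.max(np.abs(grad))),
        _trace_hinv_d=trace,
        _reference=reference,
    )
    chisq, scale = scaled_chisq(result, reference)
    object.__setattr__(result, "chisq", chisq)
    object.__setattr__(result, "scaling_factor", scale)
    return result
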