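"""Model-fit indices and information criteria.

Indices are computed from the robust-scaled chi-square.  The baseline for
the comparative fit index is the independence model at the same level
structure (diagonal covariance at both levels, free variances and means),
which has a closed-form ML solution on balanced data.  SRMR is evaluated
separately per level: the within-level pair compares the pooled
within-cluster covariance with the implied within matrix; the between-level
pair compares the saturated ANOVA estimate of the between covariance,
(n S_B - S_PW)/n, with the implied between matrix — a convention that makes
SRMR-B identically zero for the saturated-between maximum model.  Negative
diagonal entries of the between-level sample matrix are left in place for
residual computation; the affected standardized elements are skipped with a
warning, as are zero-variance elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import baseline_neg2loglik
from .moments import MomentSummary

__all__ = ["FitIndexSet", "information_criteria", "cfi", "rmsea", "srmr",
           "baseline_chisq", "compute_fit_indices"]


@dataclass(frozen=True)
class FitIndexSet:
    """Fit statistics of one fitted specification."""

    chisq: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    aic: float
    bic: float
    adj_bic: float
    srmr_within: float | None = None
    srmr_between: float | None = None
    srmr: float | None = None          # one-level specs carry a single SRMR
    baseline_chisq: float = np.nan
    baseline_df: int = 0
    baseline_ok: bool = True

    def to_dict(self) -> dict:
        out = {"chisq": self.chisq, "df": self.df, "p_value": self.p_value,
               "cfi": self.cfi, "rmsea": self.rmsea, "aic": self.aic,
               "bic": self.bic, "adj_bic": self.adj_bic}
        if self.srmr is not None:
            out["srmr"] = self.srmr
        else:
            out["srmr_within"] = self.srmr_within
            out["srmr_between"] = self.srmr_between
        return out


def information_criteria(neg2loglik: float, n_free: int, N: int):
    """AIC, BIC and sample-size-adjusted BIC from -2 ln L.

    aic = -2lnL + 2k;  bic = -2lnL + k ln N;
    adj_bic = -2lnL + k ln((N + 2)/24), with N the total observation count.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    aic = neg2loglik + 2.0 * n_free
    bic = neg2loglik + n_free * np.log(N)
    adj_bic = neg2loglik + n_free * np.log((N + 2.0) / 24.0)
    return aic, bic, adj_bic


def _stat(obj):
    """(chisq, df) from a results object or a (chisq, df) pair."""
    if hasattr(obj, "chisq"):
        return float(obj.chisq), int(obj.chisq_df)
    chisq, df = obj
    return float(chisq), int(df)


def cfi(fit, baseline) -> float:
    """Comparative fit index against the independence baseline, in [0, 1]."""
    chisq_m, df_m = _stat(fit)
    chisq_b, df_b = _stat(baseline)
    excess_m = max(chisq_m - df_m, 0.0)
    denom = max(chisq_b - df_b, excess_m, 0.0)
    if denom == 0.0:
        return 1.0
    return float(np.clip(1.0 - excess_m / denom, 0.0, 1.0))


def rmsea(fit, N: int | None = None) -> float:
    """Root mean square error of approximation, sqrt(max(chi2-df,0)/(df N))."""
    chisq, df = _stat(fit)
    if N is None:
        N = fit.nobs
    if df < 1:
        return 0.0
    return float(np.sqrt(max(chisq - df, 0.0) / (df * N)))


def _srmr_block(sample: np.ndarray, implied: np.ndarray) -> float:
    sd = np.sqrt(np.maximum(np.diag(sample), 0.0))
    P = sample.shape[0]
    resid = []
    skipped = 0
    for i in range(P):
        for j in range(i + 1):
            denom = sd[i] * sd[j]
            if denom <= 0 or not np.isfinite(denom):
                skipped += 1
                continue
            resid.append((sample[i, j] - implied[i, j]) / denom)
    if skipped:
        warnings.warn(f"srmr: skipped {skipped} element(s) with nonpositive "
                      "sample variance", stacklevel=3)
    if not resid:
        return np.nan
    return float(np.sqrt(np.mean(np.square(resid))))


def srmr(fit, moments: MomentSummary | None = None):
    """Standardized root mean squared residual(s) of a converged fit.

    Returns ``(srmr_within, srmr_between)`` for two-level specs and a single
    value for the one-level spec.
    """
    mom = moments if moments is not None else fit.moments
    imp = fit.spec.implied(fit.params.values)
    if imp.is_onelevel:
        return _srmr_block(mom.total_ml, imp.sigma_total)
    return (_srmr_block(mom.pooled_within, imp.sigma_within),
            _srmr_block(mom.between_sigma_ml(), imp.sigma_between))


def baseline_chisq(mom: MomentSummary, onelevel: bool, reference=None):
    """Robust-scaled chi-square of the independence baseline model.

    Returns (chisq, df, ok).  The baseline solution is closed-form; its
    scaling factor uses the same trace-difference correction as fitted
    models.
    """
    from .estimation import _info_at, reference_info
    from .specs import get_spec

    labels = tuple(f"v{i}" for i in range(mom.n_indicators))
    spec = get_spec("_BASE1" if onelevel else "_BASE2", labels)
    if reference is None or reference.onelevel != onelevel:
        reference = reference_info(mom, onelevel)
    df = spec.df
    value = baseline_neg2loglik(mom, onelevel)
    t_raw = max(value - reference.neg2loglik, 0.0)
    sol = spec.start_values(mom)
    _, _, trace = _info_at(spec, sol, mom)
    c = (reference.trace_hinv_d - trace) / df
    if not np.isfinite(c) or c <= 0:
        return np.nan, df, False
    return t_raw / c, df, True


def compute_fit_indices(fit) -> FitIndexSet:
    """Assemble the full fit-index set for a fitted specification."""
    mom = fit.moments
    N = mom.N
    k = fit.spec.n_params
    aic, bic, adj_bic = information_criteria(fit.neg2loglik, k, N)
    b_chisq, b_df, b_ok = baseline_chisq(mom, fit.spec.onelevel,
                                         fit._reference)
    cfi_val = cfi(fit, (b_chisq, b_df)) if b_ok else np.nan
    rmsea_val = rmsea(fit, N)
    p = (float(stats.chi2.sf(fit.chisq, fit.chisq_df))
         if fit.chisq_df > 0 else 1.0)
    srmr_val = srmr(fit, mom)
    if fit.spec.onelevel:
        srmr_w = srmr_b = None
        srmr_single = srmr_val
    else:
        srmr_w, srmr_b = srmr_val
        srmr_single = None
    return FitIndexSet(
        chisq=fit.chisq, df=fit.chisq_df, p_value=p, cfi=cfi_val,
        rmsea=rmsea_val, aic=aic, bic=bic, adj_bic=adj_bic,
        srmr_within=srmr_w, srmr_between=srmr_b, srmr=srmr_single,
        baseline_chisq=b_chisq, baseline_df=b_df, baseline_ok=b_ok,
    )
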