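"""Results container for a fitted multilevel factor model."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .moments import MomentSummary
from .specs import ModelSpec, ParameterVector

__all__ = ["MultilevelFactorResults"]


@dataclass(frozen=True)
class MultilevelFactorResults:
    """Estimates, robust standard errors and fit statistics of one fit.

    Attributes
    ----------
    params : ParameterVector
        ML estimates in the spec's free-parameter order.
    bse : ndarray
        Cluster-robust (sandwich) standard errors.
    chisq, chisq_df, scaling_factor
        Robust-scaled model chi-square against the saturated model at the
        same level structure, its degrees of freedom, and the scaling
        correction factor.
    converged, admissible
        Optimizer convergence (gradient criterion) and positive-definiteness
        of the observed information.
    """

    spec: ModelSpec
    params: ParameterVector
    bse: np.ndarray
    cov_params: np.ndarray
    neg2loglik: float
    chisq_df: int
    converged: bool
    admissible: bool
    moments: MomentSummary
    optimizer_message: str = ""
    n_iter: int = 0
    max_abs_grad: float = np.nan
    chisq: float = np.nan
    scaling_factor: float = np.nan
    _trace_hinv_d: float = field(default=np.nan, repr=False)
    _reference: object = field(default=None, repr=False)

    # ------------------------------------------------------------------
    @property
    def sample_sizes(self) -> tuple[int, int, int]:
        """(G, n, N): cluster count, cluster size, total observations."""
        return (self.moments.G, self.moments.n, self.moments.N)

    @property
    def nobs(self) -> int:
        return self.moments.N

    @property
    def chisq_unscaled(self) -> float:
        if self._reference is None:
            return np.nan
        return max(self.neg2loglik - self._reference.neg2loglik, 0.0)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params.values / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.tvalues))

    @property
    def chisq_pvalue(self) -> float:
        if self.chisq_df == 0:
            return 1.0
        return float(stats.chi2.sf(self.chisq, self.chisq_df))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Large-sample Wald intervals, estimate +/- z * robust SE."""
        z = stats.norm.ppf(1 - alpha / 2)
        est = self.params.values
        return np.column_stack((est - z * self.bse, est + z * self.bse))

    # ------------------------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        """Parameter table: name, level, kind, estimate, robust SE, z, p, CI."""
        ci = self.conf_int()
        return pd.DataFrame({
            "name": [p.name for p in self.spec.layout],
            "level": [p.level for p in self.spec.layout],
            "kind": [p.kind for p in self.spec.layout],
            "estimate": self.params.values,
            "se": self.bse,
            "z": self.tvalues,
            "p": self.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        })

    def fit_indices(self):
        """Model-fit index set (CFI, RMSEA, SRMR, information criteria)."""
        from .fit_indices import compute_fit_indices
        return compute_fit_indices(self)

    def summary(self) -> str:
        G, n, N = self.sample_sizes
        lines = [
            "Multilevel factor model results",
            "=" * 64,
            f"Specification: {self.spec.name:<10}  clusters: {G}  "
            f"cluster size: {n}  N: {N}",
            f"Converged: {self.converged}  Admissible: {self.admissible}",
            f"-2 log-likelihood: {self.neg2loglik:.3f}",
            f"Robust chi-square: {self.chisq:.3f} (df={self.chisq_df}, "
            f"p={self.chisq_pvalue:.4f}, scaling={self.scaling_factor:.3f})",
            "-" * 64,
        ]
        table = self.params_frame()
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:10.4f}".format):
            lines.append(table.to_string(index=False))
        return "\n".join(lines)

    def to_json(self) -> str:
        table = self.params_frame()
        return json.dumps({
            "spec": self.spec.name,
            "converged": self.converged,
            "admissible": self.admissible,
            "neg2loglik": self.neg2loglik,
            "chisq": None if np.isnan(self.chisq) else self.chisq,
            "df": self.chisq_df,
            "scaling_factor": (None if np.isnan(self.scaling_factor)
                               else self.scaling_factor),
            "sample_sizes": {"G": self.moments.G, "n": self.moments.n,
                             "N": self.moments.N},
            "parameters": table.replace({np.nan: None}).to_dict("records"),
        })
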