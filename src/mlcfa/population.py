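"""Population (generating) model for balanced two-level one-factor measurement data.

A two-level confirmatory factor model decomposes each observed indicator
vector into independent between-cluster and within-cluster components,

    y_ig = mu + Lambda_B eta_Bg + eps_Bg + Lambda_W eta_Wig + eps_Wig,

with eta_Bg ~ N(0, psi_B), eta_Wig ~ N(0, psi_W), and diagonal residual
covariances Theta_B, Theta_W.  The factor-level intraclass correlation is
ICC = psi_B / (psi_B + psi_W).  The default population
(:func:`harter_population`) carries the loadings, intercepts and residual
variances of a four-indicator children's perceived-competence scale measured
on students nested in classrooms, with deliberately level-varying loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PopulationModel", "harter_population", "with_icc"]

DEFAULT_LABELS = ("CPCSC", "CPCSA", "CPCAC", "CPCSW")


@dataclass(frozen=True)
class PopulationModel:
    """Generator-truth parameters of a two-level one-factor measurement model.

    The first indicator is the marker: its loading is fixed at 1 at both
    levels.  ``psi_within``/``psi_between`` may be ``None`` ("unset") until an
    ICC split is chosen with :func:`with_icc`.
    """

    within_loadings: np.ndarray
    between_loadings: np.ndarray
    theta_within: np.ndarray
    theta_between: np.ndarray
    intercepts: np.ndarray
    psi_within: float | None = None
    psi_between: float | None = None
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        for field in ("within_loadings", "between_loadings", "theta_within",
                      "theta_between", "intercepts"):
            object.__setattr__(self, field,
                               np.asarray(getattr(self, field), dtype=float))
        P = self.n_indicators
        for field in ("between_loadings", "theta_within", "theta_between",
                      "intercepts"):
            if getattr(self, field).shape != (P,):
                raise ValueError(f"{field} must have length {P}")
        if len(self.labels) != P:
            raise ValueError("labels must match the number of indicators")
        if self.within_loadings[0] != 1.0 or self.between_loadings[0] != 1.0:
            raise ValueError("marker loading (index 0) must be fixed at 1")
        if np.any(self.theta_within < 0) or np.any(self.theta_between < 0):
            raise ValueError("residual variances must be nonnegative")
        if self.psi_within is not None and self.psi_between is not None:
            if self.psi_within < 0 or self.psi_between < 0:
                raise ValueError("factor variances must be nonnegative")
            if self.psi_within + self.psi_between <= 0:
                raise ValueError("total factor variance must be positive")

    @property
    def n_indicators(self) -> int:
        return self.within_loadings.shape[0]

    @property
    def is_specified(self) -> bool:
        """Whether both level factor variances have been set."""
        return self.psi_within is not None and self.psi_between is not None

    @property
    def factor_icc(self) -> float:
        """Share of factor variance at the cluster level, psi_B/(psi_B+psi_W)."""
        if not self.is_specified:
            raise ValueError("factor variances are unset; call with_icc first")
        return self.psi_between / (self.psi_between + self.psi_within)

    def _require_specified(self):
        if not self.is_specified:
            raise ValueError("factor variances are unset; call with_icc first")

    def sigma_within(self) -> np.ndarray:
        """Model-implied within-cluster indicator covariance."""
        self._require_specified()
        lw = self.within_loadings
        return self.psi_within * np.outer(lw, lw) + np.diag(self.theta_within)

    def sigma_between(self) -> np.ndarray:
        """Model-implied between-cluster indicator covariance."""
        self._require_specified()
        lb = self.between_loadings
        return self.psi_between * np.outer(lb, lb) + np.diag(self.theta_between)

    def sigma_total(self) -> np.ndarray:
        """Total indicator covariance, the sum of the two level matrices."""
        return self.sigma_within() + self.sigma_between()

    def indicator_icc(self) -> np.ndarray:
        """Per-indicator variance share at the cluster level."""
        return np.diag(self.sigma_between()) / np.diag(self.sigma_total())

    def with_icc(self, icc: float) -> "PopulationModel":
        return with_icc(self, icc)


def harter_population() -> PopulationModel:
    """Population values of the perceived-competence scale generating model.

    Within-level loadings (1, 0.45, 0.92, 0.36), between-level loadings
    (1, 0.78, 0.60, 0.62), intercepts (2.896, 2.856, 2.860, 3.268), residual
    variances 0.5 (within) and 0.2 (between) for every indicator.  Factor
    variances are left unset; choose a split with :func:`with_icc`.
    """
    return PopulationModel(
        within_loadings=np.array([1.0, 0.45, 0.92, 0.36]),
        between_loadings=np.array([1.0, 0.78, 0.60, 0.62]),
        theta_within=np.full(4, 0.5),
        theta_between=np.full(4, 0.2),
        intercepts=np.array([2.896, 2.856, 2.860, 3.268]),
    )


def with_icc(pop: PopulationModel, icc: float) -> PopulationModel:
    """Split a unit total factor variance by the factor-level ICC.

    Sets psi_between = icc and psi_within = 1 - icc, so the total factor
    variance is 1 and ``factor_icc`` of the result equals ``icc``.  The
    boundaries 0 and 1 are allowed but degenerate one level's factor and are
    flagged with a warning.
    """
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"icc must lie in [0, 1], got {icc}")
    if icc in (0.0, 1.0):
        warnings.warn(
            f"icc={icc} degenerates the "
            f"{'within' if icc == 1.0 else 'between'}-level factor",
            stacklevel=2,
        )
    return replace(pop, psi_between=float(icc), psi_within=float(1.0 - icc))
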