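"""Sufficient statistics for balanced two-level normal likelihoods.

For a balanced design (G clusters of size n) the multivariate-normal
likelihood of any two-level covariance structure depends on the data only
through the pooled within-cluster scatter, the scatter of cluster means, and
the grand mean.  :class:`MomentSummary` stores these together with per-cluster
statistics (cluster means and within-cluster scatter matrices), which are the
independent-unit contributions needed for cluster-robust inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .sampling import TwoLevelSample

__all__ = ["MomentSummary", "compute_moments", "implied_covariances",
           "ImpliedCovariances"]


@dataclass(frozen=True)
class MomentSummary:
    """Balanced-design sufficient statistics.

    ``pooled_within`` uses the maximum-likelihood divisor N - G.
    ``between_ml`` is the covariance of cluster means about the grand mean
    with the ML divisor G; the descriptive (G - 1) version is available as
    :attr:`between_means`.
    """

    pooled_within: np.ndarray    # P x P, divisor N - G
    between_ml: np.ndarray       # P x P covariance of cluster means, divisor G
    grand_mean: np.ndarray       # length P
    cluster_means: np.ndarray    # G x P
    within_scatter: np.ndarray   # G x P x P, per-cluster centered scatter
    n: int
    G: int

    @property
    def N(self) -> int:
        return self.n * self.G

    @property
    def n_indicators(self) -> int:
        return self.grand_mean.shape[0]

    @property
    def between_means(self) -> np.ndarray:
        """Descriptive covariance of cluster means (divisor G - 1)."""
        return self.between_ml * self.G / (self.G - 1)

    @property
    def total_ml(self) -> np.ndarray:
        """ML total covariance (divisor N) about the grand mean."""
        return ((self.N - self.G) * self.pooled_within
                + self.n * self.G * self.between_ml) / self.N

    def between_sigma_ml(self) -> np.ndarray:
        """ANOVA estimate of the between-level covariance, (n S_n - S_PW)/n.

        This is the saturated-model ML estimate of Sigma_B on balanced data;
        it may have negative diagonal entries in small samples.
        """
        return self.between_ml - self.pooled_within / self.n

    def to_json(self) -> str:
        return json.dumps({
            "pooled_within": self.pooled_within.tolist(),
            "between_ml": self.between_ml.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "n": self.n,
            "G": self.G,
        })


def compute_moments(sample: TwoLevelSample) -> MomentSummary:
    """Reduce a balanced sample to its sufficient statistics.

    Raises if there are fewer than two clusters or if every cluster is a
    singleton (the pooled-within divisor N - G would vanish).
    """
    G, n = sample.cluster_number, sample.cluster_size
    if G < 2:
        raise ValueError("at least two clusters are required")
    if n < 2:
        raise ValueError("pooled within-cluster covariance is undefined "
                         "for singleton clusters (N - G = 0)")
    P = sample.n_indicators
    # order rows by cluster so the balanced reshape is valid
    order = np.argsort(sample.cluster_ids, kind="stable")
    y = sample.responses[order].reshape(G, n, P)

    cluster_means = y.mean(axis=1)
    grand_mean = cluster_means.mean(axis=0)
    dev_w = y - cluster_means[:, None, :]
    within_scatter = np.einsum("gnp,gnq->gpq", dev_w, dev_w)
    pooled_within = within_scatter.sum(axis=0) / (G * n - G)
    dev_b = cluster_means - grand_mean
    between_ml = dev_b.T @ dev_b / G

    return MomentSummary(
        pooled_within=pooled_within,
        between_ml=between_ml,
        grand_mean=grand_mean,
        cluster_means=cluster_means,
        within_scatter=within_scatter,
        n=n,
        G=G,
    )


@dataclass(frozen=True)
class ImpliedCovariances:
    """Model-implied covariance matrices (and means) of one specification."""

    mu: np.ndarray
    sigma_within: np.ndarray | None = None
    sigma_between: np.ndarray | None = None
    sigma_total: np.ndarray | None = None

    @property
    def is_onelevel(self) -> bool:
        return self.sigma_total is not None


def implied_covariances(spec, params) -> ImpliedCovariances:
    """Evaluate a specification's structured matrices at a parameter vector.

    ``spec`` is a :class:`~mlcfa.specs.ModelSpec` (or its name) and ``params``
    a :class:`~mlcfa.specs.ParameterVector` or plain array conforming to the
    spec's layout.
    """
    from .specs import get_spec, ParameterVector

    spec = get_spec(spec)
    if isinstance(params, ParameterVector):
        if params.spec.name != spec.name:
            raise ValueError("parameter vector does not match the spec")
        values = params.values
    else:
        values = np.asarray(params, dtype=float)
        if values.shape != (spec.n_params,):
            raise ValueError(
                f"expected {spec.n_params} parameters for {spec.name}, "
                f"got {values.shape}")
    return spec.implied(values)
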