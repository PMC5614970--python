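"""statsmodels-style model facade.

    >>> model = MultilevelFactorModel.from_dataframe(df, cluster_col="cluster_id",
    ...                                              spec="2MLR")
    >>> res = model.fit()
    >>> print(res.summary())

The heavy lifting lives in :mod:`mlcfa.estimation`; this class packages a
balanced clustered sample with a specification and hands back a
:class:`~mlcfa.results.MultilevelFactorResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import estimation
from .moments import compute_moments
from .results import MultilevelFactorResults
from .sampling import TwoLevelSample
from .specs import get_spec

__all__ = ["MultilevelFactorModel"]


class MultilevelFactorModel:
    """A one-factor measurement model for balanced clustered data.

    Parameters
    ----------
    endog : array-like, N x P
        Indicator responses, one row per individual.
    clusters : array-like, length N
        Cluster labels; every label must occur equally often (balanced).
    spec : str
        ``2MLR`` (two-level, the default), ``1MLR`` (one level with
        cluster-robust SEs), ``2MaxB``, ``2MaxW`` or ``2Miss``.
    labels : sequence of str, optional
        Indicator names; defaults to the perceived-competence scale labels
        for P = 4, else ``y1..yP``.
    """

    def __init__(self, endog, clusters, spec: str = "2MLR", labels=None):
        endog = np.asarray(endog, dtype=float)
        if labels is None:
            if endog.shape[1] == 4:
                from .population import DEFAULT_LABELS
                labels = DEFAULT_LABELS
            else:
                labels = tuple(f"y{i + 1}" for i in range(endog.shape[1]))
        clusters = np.asarray(clusters)
        _, counts = np.unique(clusters, return_counts=True)
        if len(set(counts)) != 1:
            raise ValueError("unbalanced designs are not supported")
        self.sample = TwoLevelSample(
            responses=endog, cluster_ids=clusters,
            cluster_size=int(counts[0]), cluster_number=len(counts),
            labels=tuple(labels))
        self.spec = get_spec(spec, tuple(labels))
        self.moments = compute_moments(self.sample)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cluster_col: str = "cluster_id",
                       indicators=None, spec: str = "2MLR"
                       ) -> "MultilevelFactorModel":
        """Build from a long-format frame: one row per individual."""
        if indicators is None:
            indicators = [c for c in df.columns if c != cluster_col]
        return cls(df[list(indicators)].to_numpy(dtype=float),
                   df[cluster_col].to_numpy(), spec=spec,
                   labels=tuple(indicators))

    @classmethod
    def from_sample(cls, sample: TwoLevelSample, spec: str = "2MLR"
                    ) -> "MultilevelFactorModel":
        return cls(sample.responses, sample.cluster_ids, spec=spec,
                   labels=sample.labels)

    @classmethod
    def from_csv(cls, path, cluster_col: str = "cluster_id",
                 spec: str = "2MLR") -> "MultilevelFactorModel":
        return cls.from_sample(
            TwoLevelSample.from_csv(path, cluster_col=cluster_col), spec=spec)

    def fit(self, start=None, gtol: float = 1e-5, maxiter: int = 2000,
            reference=None) -> MultilevelFactorResults:
        """Maximize the likelihood; never raises on routine non-convergence."""
        return estimation.fit(self.spec, self.moments, start=start,
                              gtol=gtol, maxiter=maxiter, reference=reference)
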