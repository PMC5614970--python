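"""Balanced two-level dataset generation and CSV interchange.

Datasets are drawn from a :class:`~mlcfa.population.PopulationModel`: each
cluster receives a between-level factor score and residual vector, each member
a within-level factor score and residual vector, all normal and mutually
independent.  Random streams are keyed by (condition seed, condition identity,
replicate index), so any replicate of any condition can be regenerated in
isolation and conditions can be processed in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .population import PopulationModel, with_icc

__all__ = [
    "SimulationCondition",
    "TwoLevelSample",
    "generate_dataset",
    "generate_grid",
]


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design: (CN, CS, ICC, replications, seed)."""

    cluster_number: int
    cluster_size: int
    icc: float
    replications: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.cluster_number < 2:
            raise ValueError("cluster_number must be >= 2")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("icc must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return self.cluster_number * self.cluster_size

    def identity_key(self) -> tuple[int, int, int]:
        """Integer key identifying the condition inside seed derivation."""
        return (self.cluster_number, self.cluster_size, round(self.icc * 10**6))


@dataclass(frozen=True)
class TwoLevelSample:
    """A balanced clustered response matrix with cluster labels."""

    responses: np.ndarray          # N x P
    cluster_ids: np.ndarray        # length N
    cluster_size: int
    cluster_number: int
    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "responses",
                           np.asarray(self.responses, dtype=float))
        object.__setattr__(self, "cluster_ids", np.asarray(self.cluster_ids))
        N = self.cluster_number * self.cluster_size
        if self.responses.shape[0] != N:
            raise ValueError("responses must have N = G * n rows")
        if self.cluster_ids.shape[0] != N:
            raise ValueError("cluster_ids must have length N")
        _, counts = np.unique(self.cluster_ids, return_counts=True)
        if len(counts) != self.cluster_number or np.any(counts != self.cluster_size):
            raise ValueError("every cluster label must occur exactly n times")

    @property
    def n_total(self) -> int:
        return self.responses.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.responses.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=list(self.labels))
        df.insert(0, "cluster_id", self.cluster_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       cluster_col: str = "cluster_id") -> "TwoLevelSample":
        if cluster_col not in df.columns:
            raise ValueError(f"missing cluster column {cluster_col!r}")
        indicators = [c for c in df.columns if c != cluster_col]
        ids = df[cluster_col].to_numpy()
        _, counts = np.unique(ids, return_counts=True)
        if len(set(counts)) != 1:
            raise ValueError("unbalanced designs are not supported")
        return cls(
            responses=df[indicators].to_numpy(dtype=float),
            cluster_ids=ids,
            cluster_size=int(counts[0]),
            cluster_number=len(counts),
            labels=tuple(indicators),
        )

    @classmethod
    def from_csv(cls, path, cluster_col: str = "cluster_id") -> "TwoLevelSample":
        return cls.from_dataframe(pd.read_csv(path), cluster_col=cluster_col)


def _rng_for(condition: SimulationCondition, replicate_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=condition.seed,
        spawn_key=(*condition.identity_key(), replicate_index),
    )
    return np.random.default_rng(ss)


def generate_dataset(pop: PopulationModel, condition: SimulationCondition,
                     replicate_index: int = 0) -> TwoLevelSample:
    """Draw one balanced two-level dataset.

    ``pop`` must be fully specified (factor variances set).  The draw is a
    pure function of ``(condition.seed, condition identity, replicate_index)``.
    """
    pop._require_specified()
    G, n, P = condition.cluster_number, condition.cluster_size, pop.n_indicators
    rng = _rng_for(condition, replicate_index)

    eta_b = rng.normal(0.0, np.sqrt(pop.psi_between), size=G)
    eps_b = rng.normal(0.0, np.sqrt(pop.theta_between), size=(G, P))
    eta_w = rng.normal(0.0, np.sqrt(pop.psi_within), size=(G, n))
    eps_w = rng.normal(0.0, np.sqrt(pop.theta_within), size=(G, n, P))

    between = pop.intercepts + eta_b[:, None] * pop.between_loadings + eps_b
    within = eta_w[:, :, None] * pop.within_loadings + eps_w
    responses = (between[:, None, :] + within).reshape(G * n, P)

    return TwoLevelSample(
        responses=responses,
        cluster_ids=np.repeat(np.arange(G), n),
        cluster_size=n,
        cluster_number=G,
        labels=pop.labels,
    )


def generate_grid(
    pop: PopulationModel,
    conditions: Iterable[SimulationCondition],
) -> Iterator[tuple[SimulationCondition, int, TwoLevelSample]]:
    """Lazily enumerate all replications of all conditions.

    The population's factor variance split is (re)derived from each
    condition's ICC, so an unspecified base population is accepted.  The
    stream is deterministic under fixed seeds and independent of enumeration
    order because substreams are keyed by condition identity.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition list must be nonempty")
    import warnings as _warnings

    for condition in conditions:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # boundary ICCs are deliberate here
            pop_c = with_icc(pop, condition.icc)
        for rep in range(condition.replications):
            yield condition, rep, generate_dataset(pop_c, condition, rep)
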