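"""Study configuration: YAML/JSON schema, validation, condition grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .population import PopulationModel, harter_population
from .sampling import SimulationCondition
from .specs import MODEL_SPEC_NAMES

__all__ = ["StudyConfig", "load_config"]

_ALLOWED_KEYS = {
    "labels", "loadings_within", "loadings_between", "theta_within",
    "theta_between", "intercepts", "icc_list", "cn_list", "cs_list",
    "replications", "seed", "specs", "compute_indices",
}


@dataclass(frozen=True)
class StudyConfig:
    """Population values plus the factorial (CN, CS, ICC) grid."""

    cn_list: tuple[int, ...]
    cs_list: tuple[int, ...]
    icc_list: tuple[float, ...]
    replications: int = 1000
    seed: int = 0
    specs: tuple[str, ...] = MODEL_SPEC_NAMES
    compute_indices: bool = True
    labels: tuple[str, ...] | None = None
    loadings_within: tuple[float, ...] | None = None
    loadings_between: tuple[float, ...] | None = None
    theta_within: tuple[float, ...] | None = None
    theta_between: tuple[float, ...] | None = None
    intercepts: tuple[float, ...] | None = None

    def __post_init__(self):
        unknown = [s for s in self.specs if s not in MODEL_SPEC_NAMES]
        if unknown:
            raise ValueError(f"unknown specs {unknown}; "
                             f"choose from {MODEL_SPEC_NAMES}")
        custom = [self.loadings_within, self.loadings_between,
                  self.theta_within, self.theta_between, self.intercepts]
        if any(v is not None for v in custom) and not all(
                v is not None for v in custom):
            raise ValueError("a custom population requires all of "
                             "loadings_within, loadings_between, "
                             "theta_within, theta_between, intercepts")

    def population(self) -> PopulationModel:
        """The generating model (factor variances still unset)."""
        if self.loadings_within is None:
            return harter_population()
        labels = self.labels or tuple(
            f"y{i + 1}" for i in range(len(self.loadings_within)))
        return PopulationModel(
            within_loadings=self.loadings_within,
            between_loadings=self.loadings_between,
            theta_within=self.theta_within,
            theta_between=self.theta_between,
            intercepts=self.intercepts,
            labels=labels,
        )

    def conditions(self) -> list[SimulationCondition]:
        """The full factorial grid, in (CN, CS, ICC) lexical order."""
        return [
            SimulationCondition(cluster_number=cn, cluster_size=cs, icc=icc,
                                replications=self.replications, seed=self.seed)
            for cn in self.cn_list
            for cs in self.cs_list
            for icc in self.icc_list
        ]


def load_config(path) -> StudyConfig:
    """Read and validate a YAML (or JSON) study configuration.

    Unknown keys are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("cn_list", "cs_list", "icc_list"):
        if key not in raw:
            raise ValueError(f"missing required key {key!r}")
    tup = lambda v: tuple(v) if isinstance(v, (list, tuple)) else v  # noqa: E731
    return StudyConfig(**{k: tup(v) for k, v in raw.items()})
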