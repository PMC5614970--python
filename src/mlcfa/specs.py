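"""Parameter layouts of the analytic model specifications.

Five user-facing specifications are compared on balanced two-level data:

``2MLR``
    the two-level one-factor model with free loadings at each level (the
    data-generating structure);
``2Miss``
    the two-level model with between- and within-level loadings constrained
    equal (a deliberately misspecified variant);
``1MLR``
    a single-level one-factor model fitted to the total covariance, with
    cluster-robust standard errors (the design-based approach);
``2MaxB`` / ``2MaxW``
    "maximum" models that saturate one level's covariance matrix (all unique
    elements free) while structuring the other.

In every spec the first indicator is the marker (loading fixed at 1, absent
from the free layout) and the P indicator means are free.  Hidden reference
specs (saturated and independence models at each level structure) share the
same machinery and have closed-form ML solutions on balanced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .moments import ImpliedCovariances, MomentSummary
from .population import DEFAULT_LABELS

__all__ = ["ParameterInfo", "ParameterVector", "ModelSpec", "get_spec",
           "MODEL_SPEC_NAMES"]

MODEL_SPEC_NAMES = ("2MLR", "1MLR", "2MaxB", "2MaxW", "2Miss")

KINDS = ("loading", "factor_variance", "residual_variance", "covariance", "mean")


@dataclass(frozen=True)
class ParameterInfo:
    """One free parameter: display name, level, kind and indicator label(s)."""

    name: str
    level: str          # "within" | "between" | "both" | "overall"
    kind: str
    indicator: str | None = None


@dataclass(frozen=True)
class ParameterVector:
    """An ordered real vector matching a spec's free-parameter layout."""

    values: np.ndarray
    spec: "ModelSpec"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (self.spec.n_params,):
            raise ValueError(
                f"{self.spec.name} expects {self.spec.n_params} parameters, "
                f"got {self.values.shape}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=[p.name for p in self.spec.layout])

    def __getitem__(self, name: str) -> float:
        names = [p.name for p in self.spec.layout]
        return float(self.values[names.index(name)])


@dataclass(frozen=True)
class ModelSpec:
    """A model specification: layout, implied-matrix builder, start values."""

    name: str
    labels: tuple[str, ...]
    layout: tuple[ParameterInfo, ...]
    onelevel: bool
    _implied: Callable[[np.ndarray], ImpliedCovariances]
    _start: Callable[[MomentSummary], np.ndarray]
    _implied_grad: Callable[[np.ndarray], tuple] | None = None
    hidden: bool = field(default=False)

    @property
    def n_params(self) -> int:
        return len(self.layout)

    @property
    def n_indicators(self) -> int:
        return len(self.labels)

    @property
    def n_sample_moments(self) -> int:
        """Count of saturated moments at this level structure (incl. means)."""
        P = self.n_indicators
        cov = P * (P + 1) // 2
        return (cov if self.onelevel else 2 * cov) + P

    @property
    def df(self) -> int:
        """Degrees of freedom of the model chi-square."""
        return self.n_sample_moments - self.n_params

    def implied(self, values: np.ndarray) -> ImpliedCovariances:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_params,):
            raise ValueError(
                f"{self.name} expects {self.n_params} parameters")
        return self._implied(values)

    def start_values(self, moments: MomentSummary) -> np.ndarray:
        return self._start(moments)

    def implied_grad(self, values: np.ndarray):
        """Structure derivatives at ``values``.

        Returns ``(dmu, d_sigma_within, d_sigma_between)`` for two-level
        specs and ``(dmu, d_sigma_total)`` for one-level specs, with leading
        dimension the free-parameter index.
        """
        return self._implied_grad(np.asarray(values, dtype=float))

    def parameter_vector(self, values) -> ParameterVector:
        return ParameterVector(np.asarray(values, dtype=float), self)


# ---------------------------------------------------------------------------
# layout builders

def _factor_layout(labels, suffix, level):
    """Loadings (non-marker), factor variance, residual variances."""
    out = [ParameterInfo(f"lambda{suffix}[{lab}]", level, "loading", lab)
           for lab in labels[1:]]
    out.append(ParameterInfo(f"psi{suffix}", level, "factor_variance"))
    out += [ParameterInfo(f"theta{suffix}[{lab}]", level, "residual_variance", lab)
            for lab in labels]
    return out


def _vech_layout(labels, suffix, level):
    P = len(labels)
    out = []
    for i in range(P):
        for j in range(i + 1):
            kind = "residual_variance" if i == j else "covariance"
            out.append(ParameterInfo(
                f"sigma{suffix}[{labels[i]},{labels[j]}]", level, kind,
                f"{labels[i]},{labels[j]}" if i != j else labels[i]))
    return out


def _mean_layout(labels, level):
    return [ParameterInfo(f"mu[{lab}]", level, "mean", lab) for lab in labels]


def _factor_block(vals, P):
    """(loadings..., psi, theta...) -> covariance matrix; consumes 2P params."""
    lam = np.concatenate(([1.0], vals[:P - 1]))
    psi = vals[P - 1]
    theta = vals[P:2 * P]
    return psi * np.outer(lam, lam) + np.diag(theta)


def _vech_block(vals, P):
    out = np.zeros((P, P))
    idx = np.tril_indices(P)
    out[idx] = vals
    return out + np.tril(out, -1).T


def _vech(mat):
    return mat[np.tril_indices(mat.shape[0])]


# structure derivatives -----------------------------------------------------

def _factor_block_grad(vals, P):
    """Derivatives of a factor block w.r.t. its 2P parameters: (2P, P, P)."""
    lam = np.concatenate(([1.0], vals[:P - 1]))
    psi = vals[P - 1]
    out = np.zeros((2 * P, P, P))
    for p in range(1, P):
        E = np.zeros((P, P))
        E[p, :] += lam
        E[:, p] += lam
        out[p - 1] = psi * E
    out[P - 1] = np.outer(lam, lam)
    for p in range(P):
        out[P + p, p, p] = 1.0
    return out


def _vech_block_grad(P):
    """Constant derivatives of a saturated block: (P(P+1)/2, P, P)."""
    nv = P * (P + 1) // 2
    out = np.zeros((nv, P, P))
    for k, (i, j) in enumerate(zip(*np.tril_indices(P))):
        out[k, i, j] = out[k, j, i] = 1.0
    return out


def _diag_block_grad(P):
    out = np.zeros((P, P, P))
    for p in range(P):
        out[p, p, p] = 1.0
    return out


# ---------------------------------------------------------------------------
# start-value helpers (deterministic, scale-aware; loadings start at 0.7,
# factor variances at half the marker variance of the relevant level,
# residual variances at half the observed diagonals, means at grand means)

_THETA_FLOOR = 1e-3


def _start_factor(S, P):
    psi0 = 0.5 * S[0, 0]
    theta0 = np.maximum(0.5 * np.diag(S), _THETA_FLOOR * S[0, 0])
    return np.concatenate((np.full(P - 1, 0.7), [psi0], theta0))


# ---------------------------------------------------------------------------
# spec constructors

def _make_2mlr(labels):
    P = len(labels)
    layout = tuple(_factor_layout(labels, "_w", "within")
                   + _factor_layout(labels, "_b", "between")
                   + _mean_layout(labels, "both"))

    def implied(v):
        return ImpliedCovariances(
            mu=v[4 * P:],
            sigma_within=_factor_block(v[:2 * P], P),
            sigma_between=_factor_block(v[2 * P:4 * P], P),
        )

    def start(mom):
        return np.concatenate((
            _start_factor(mom.pooled_within, P),
            _start_factor(mom.between_ml, P),
            mom.grand_mean,
        ))

    def grad(v):
        k = 5 * P
        dSw = np.zeros((k, P, P))
        dSb = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSw[:2 * P] = _factor_block_grad(v[:2 * P], P)
        dSb[2 * P:4 * P] = _factor_block_grad(v[2 * P:4 * P], P)
        dmu[4 * P:] = np.eye(P)
        return dmu, dSw, dSb

    return ModelSpec("2MLR", labels, layout, False, implied, start, grad)


def _make_2miss(labels):
    P = len(labels)
    layout = tuple(
        [ParameterInfo(f"lambda[{lab}]", "both", "loading", lab)
         for lab in labels[1:]]
        + [ParameterInfo("psi_w", "within", "factor_variance")]
        + [ParameterInfo(f"theta_w[{lab}]", "within", "residual_variance", lab)
           for lab in labels]
        + [ParameterInfo("psi_b", "between", "factor_variance")]
        + [ParameterInfo(f"theta_b[{lab}]", "between", "residual_variance", lab)
           for lab in labels]
        + _mean_layout(labels, "both"))

    def implied(v):
        lam = np.concatenate(([1.0], v[:P - 1]))
        outer = np.outer(lam, lam)
        psi_w, theta_w = v[P - 1], v[P:2 * P]
        psi_b, theta_b = v[2 * P], v[2 * P + 1:3 * P + 1]
        return ImpliedCovariances(
            mu=v[3 * P + 1:],
            sigma_within=psi_w * outer + np.diag(theta_w),
            sigma_between=psi_b * outer + np.diag(theta_b),
        )

    def start(mom):
        sw = _start_factor(mom.pooled_within, P)
        sb = _start_factor(mom.between_ml, P)
        return np.concatenate((sw[:P], sw[P:2 * P], sb[P - 1:2 * P],
                               mom.grand_mean))

    def grad(v):
        k = 4 * P + 1
        lam = np.concatenate(([1.0], v[:P - 1]))
        psi_w, psi_b = v[P - 1], v[2 * P]
        dSw = np.zeros((k, P, P))
        dSb = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        outer = np.outer(lam, lam)
        for p in range(1, P):  # shared loadings drive both levels
            E = np.zeros((P, P))
            E[p, :] += lam
            E[:, p] += lam
            dSw[p - 1] = psi_w * E
            dSb[p - 1] = psi_b * E
        dSw[P - 1] = outer
        dSw[P:2 * P] = _diag_block_grad(P)
        dSb[2 * P] = outer
        dSb[2 * P + 1:3 * P + 1] = _diag_block_grad(P)
        dmu[3 * P + 1:] = np.eye(P)
        return dmu, dSw, dSb

    return ModelSpec("2Miss", labels, layout, False, implied, start, grad)


def _make_2maxb(labels):
    P = len(labels)
    nv = P * (P + 1) // 2
    layout = tuple(_vech_layout(labels, "_b", "between")
                   + _factor_layout(labels, "_w", "within")
                   + _mean_layout(labels, "both"))

    def implied(v):
        return ImpliedCovariances(
            mu=v[nv + 2 * P:],
            sigma_within=_factor_block(v[nv:nv + 2 * P], P),
            sigma_between=_vech_block(v[:nv], P),
        )

    def start(mom):
        return np.concatenate((_vech(mom.between_ml),
                               _start_factor(mom.pooled_within, P),
                               mom.grand_mean))

    def grad(v):
        k = nv + 3 * P
        dSw = np.zeros((k, P, P))
        dSb = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSb[:nv] = _vech_block_grad(P)
        dSw[nv:nv + 2 * P] = _factor_block_grad(v[nv:nv + 2 * P], P)
        dmu[nv + 2 * P:] = np.eye(P)
        return dmu, dSw, dSb

    return ModelSpec("2MaxB", labels, layout, False, implied, start, grad)


def _make_2maxw(labels):
    P = len(labels)
    nv = P * (P + 1) // 2
    layout = tuple(_factor_layout(labels, "_b", "between")
                   + _vech_layout(labels, "_w", "within")
                   + _mean_layout(labels, "both"))

    def implied(v):
        return ImpliedCovariances(
            mu=v[2 * P + nv:],
            sigma_within=_vech_block(v[2 * P:2 * P + nv], P),
            sigma_between=_factor_block(v[:2 * P], P),
        )

    def start(mom):
        return np.concatenate((_start_factor(mom.between_ml, P),
                               _vech(mom.pooled_within),
                               mom.grand_mean))

    def grad(v):
        k = nv + 3 * P
        dSw = np.zeros((k, P, P))
        dSb = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSb[:2 * P] = _factor_block_grad(v[:2 * P], P)
        dSw[2 * P:2 * P + nv] = _vech_block_grad(P)
        dmu[2 * P + nv:] = np.eye(P)
        return dmu, dSw, dSb

    return ModelSpec("2MaxW", labels, layout, False, implied, start, grad)


def _make_1mlr(labels):
    P = len(labels)
    layout = tuple(
        [ParameterInfo(f"lambda[{lab}]", "overall", "loading", lab)
         for lab in labels[1:]]
        + [ParameterInfo("psi", "overall", "factor_variance")]
        + [ParameterInfo(f"theta[{lab}]", "overall", "residual_variance", lab)
           for lab in labels]
        + _mean_layout(labels, "overall"))

    def implied(v):
        return ImpliedCovariances(mu=v[2 * P:],
                                  sigma_total=_factor_block(v[:2 * P], P))

    def start(mom):
        return np.concatenate((_start_factor(mom.total_ml, P), mom.grand_mean))

    def grad(v):
        k = 3 * P
        dSt = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSt[:2 * P] = _factor_block_grad(v[:2 * P], P)
        dmu[2 * P:] = np.eye(P)
        return dmu, dSt

    return ModelSpec("1MLR", labels, layout, True, implied, start, grad)


def _make_sat2(labels):
    P = len(labels)
    nv = P * (P + 1) // 2
    layout = tuple(_vech_layout(labels, "_w", "within")
                   + _vech_layout(labels, "_b", "between")
                   + _mean_layout(labels, "both"))

    def implied(v):
        return ImpliedCovariances(
            mu=v[2 * nv:],
            sigma_within=_vech_block(v[:nv], P),
            sigma_between=_vech_block(v[nv:2 * nv], P),
        )

    def start(mom):  # exact ML solution on balanced data
        return np.concatenate((
            _vech(mom.pooled_within),
            _vech(mom.between_sigma_ml()),
            mom.grand_mean,
        ))

    def grad(v):
        k = 2 * nv + P
        dSw = np.zeros((k, P, P))
        dSb = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSw[:nv] = _vech_block_grad(P)
        dSb[nv:2 * nv] = _vech_block_grad(P)
        dmu[2 * nv:] = np.eye(P)
        return dmu, dSw, dSb

    return ModelSpec("_SAT2", labels, layout, False, implied, start, grad,
                     hidden=True)


def _make_sat1(labels):
    P = len(labels)
    nv = P * (P + 1) // 2
    layout = tuple(_vech_layout(labels, "", "overall")
                   + _mean_layout(labels, "overall"))

    def implied(v):
        return ImpliedCovariances(mu=v[nv:], sigma_total=_vech_block(v[:nv], P))

    def start(mom):
        return np.concatenate((_vech(mom.total_ml), mom.grand_mean))

    def grad(v):
        k = nv + P
        dSt = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSt[:nv] = _vech_block_grad(P)
        dmu[nv:] = np.eye(P)
        return dmu, dSt

    return ModelSpec("_SAT1", labels, layout, True, implied, start, grad,
                     hidden=True)


def _make_base2(labels):
    P = len(labels)
    layout = tuple(
        [ParameterInfo(f"var_w[{lab}]", "within", "residual_variance", lab)
         for lab in labels]
        + [ParameterInfo(f"var_b[{lab}]", "between", "residual_variance", lab)
           for lab in labels]
        + _mean_layout(labels, "both"))

    def implied(v):
        return ImpliedCovariances(mu=v[2 * P:],
                                  sigma_within=np.diag(v[:P]),
                                  sigma_between=np.diag(v[P:2 * P]))

    def start(mom):  # exact ML solution (diagonalized saturated estimates)
        return np.concatenate((
            np.diag(mom.pooled_within),
            np.diag(mom.between_sigma_ml()),
            mom.grand_mean,
        ))

    def grad(v):
        k = 3 * P
        dSw = np.zeros((k, P, P))
        dSb = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSw[:P] = _diag_block_grad(P)
        dSb[P:2 * P] = _diag_block_grad(P)
        dmu[2 * P:] = np.eye(P)
        return dmu, dSw, dSb

    return ModelSpec("_BASE2", labels, layout, False, implied, start, grad,
                     hidden=True)


def _make_base1(labels):
    P = len(labels)
    layout = tuple(
        [ParameterInfo(f"var[{lab}]", "overall", "residual_variance", lab)
         for lab in labels]
        + _mean_layout(labels, "overall"))

    def implied(v):
        return ImpliedCovariances(mu=v[P:], sigma_total=np.diag(v[:P]))

    def start(mom):
        return np.concatenate((np.diag(mom.total_ml), mom.grand_mean))

    def grad(v):
        k = 2 * P
        dSt = np.zeros((k, P, P))
        dmu = np.zeros((k, P))
        dSt[:P] = _diag_block_grad(P)
        dmu[P:] = np.eye(P)
        return dmu, dSt

    return ModelSpec("_BASE1", labels, layout, True, implied, start, grad,
                     hidden=True)


_FACTORIES = {
    "2MLR": _make_2mlr,
    "2Miss": _make_2miss,
    "2MaxB": _make_2maxb,
    "2MaxW": _make_2maxw,
    "1MLR": _make_1mlr,
    "_SAT2": _make_sat2,
    "_SAT1": _make_sat1,
    "_BASE2": _make_base2,
    "_BASE1": _make_base1,
}

_CACHE: dict[tuple[str, tuple[str, ...]], ModelSpec] = {}


def get_spec(name, labels: tuple[str, ...] = DEFAULT_LABELS) -> ModelSpec:
    """Look up (or pass through) a model specification.

    ``name`` may be a :class:`ModelSpec` already, or one of ``2MLR``,
    ``1MLR``, ``2MaxB``, ``2MaxW``, ``2Miss``.
    """
    if isinstance(name, ModelSpec):
        return name
    labels = tuple(labels)
    key = (name, labels)
    if key not in _CACHE:
        if name not in _FACTORIES:
            raise KeyError(f"unknown model specification {name!r}; "
                           f"choose from {MODEL_SPEC_NAMES}")
        _CACHE[key] = _FACTORIES[name](labels)
    return _CACHE[key]
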