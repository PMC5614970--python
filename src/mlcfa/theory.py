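"""Closed-form conflation and reliability theory.

When a single-level factor model is fitted to clustered data whose loadings
differ by level, the probability limit of each loading is (approximately) the
ICC-weighted average of its between- and within-level population values,

    lambda_y = ICC * lambda_B + (1 - ICC) * lambda_W,

exact at ICC = 0 and 1.  The exact probability limit is obtained here by
fitting the one-level model to the population total covariance
Sigma_B + Sigma_W directly (no sampling), against which the weighted-average
formula is an approximation.

Composite reliability of a congeneric scale is
rho = (sum lambda)^2 psi / [(sum lambda)^2 psi + sum theta]; the design-based
variant squares the ICC-weighted between- and within-loading totals
*separately* before summing:

    rho_DB = [ (ICC * sum lambda_B)^2 + ((1-ICC) * sum lambda_W)^2 ]
             / { same + sum(theta_B + theta_W) }.

Because (a^2 + b^2) < (a + b)^2 for positive a, b, this is strictly smaller
than feeding the conflated loadings through the congeneric formula whenever
both weighted sums are positive; the two definitions are kept distinct
rather than silently reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .population import PopulationModel
from .specs import ParameterVector, get_spec

__all__ = ["conflated_loadings", "pseudo_true_onelevel",
           "composite_reliability", "design_based_reliability",
           "indicator_r2", "DerivedQuantities", "derived_quantities",
           "conflation_curve"]


def conflated_loadings(pop: PopulationModel) -> np.ndarray:
    """ICC-weighted average of between- and within-level loadings."""
    icc = pop.factor_icc
    return icc * pop.between_loadings + (1.0 - icc) * pop.within_loadings


def pseudo_true_onelevel(pop: PopulationModel, gtol: float = 1e-8
                         ) -> ParameterVector:
    """Probability limit of the one-level (design-based) ML estimates.

    Fits the single-level one-factor model to the exact population total
    covariance Sigma_B + Sigma_W by minimizing the ML discrepancy
    ln|Sigma(theta)| + tr(Sigma(theta)^-1 Sigma_pop); no sampling is
    involved.  The conflated-loading formula approximates the loadings of
    this solution.
    """
    spec = get_spec("1MLR", pop.labels)
    P = pop.n_indicators
    target = pop.sigma_total()

    def discrepancy(x):
        imp = spec.implied(np.concatenate((x, pop.intercepts)))
        sig = imp.sigma_total
        try:
            c = np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return logdet + np.trace(np.linalg.solve(sig, target))

    x0 = np.concatenate((np.full(P - 1, 0.7), [0.5 * target[0, 0]],
                         0.5 * np.diag(target)))
    opt = minimize(discrepancy, x0, method="L-BFGS-B",
                   options={"ftol": 1e-16, "gtol": gtol, "maxiter": 5000})
    if not np.isfinite(opt.fun) or opt.fun >= 1e10:
        raise RuntimeError("pseudo-true one-level fit did not converge")
    return spec.parameter_vector(np.concatenate((opt.x, pop.intercepts)))


def composite_reliability(loadings, theta, psi: float = 1.0) -> float:
    """Congeneric-scale composite reliability.

    rho = (sum lambda)^2 psi / [(sum lambda)^2 psi + sum theta]; at unit
    factor variance this is the textbook form.  The explicit psi multiplier
    makes the measure invariant to the marker-scaling convention
    (lambda -> c lambda, psi -> psi / c^2).
    """
    loadings = np.asarray(loadings, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or psi < 0:
        raise ValueError("variances must be nonnegative")
    common = loadings.sum() ** 2 * psi
    denom = common + theta.sum()
    if denom == 0:
        raise ValueError("reliability undefined: zero total variance")
    return float(common / denom)


def design_based_reliability(pop: PopulationModel) -> float:
    """Reliability of the conflated one-level composite, level-decomposed form.

    The ICC-weighted between-loading total and the (1-ICC)-weighted
    within-loading total are squared separately; the error term pools both
    levels' residual variances.
    """
    icc = pop.factor_icc
    a = icc * pop.between_loadings.sum()
    b = (1.0 - icc) * pop.within_loadings.sum()
    common = a ** 2 + b ** 2
    return float(common / (common
                           + pop.theta_between.sum() + pop.theta_within.sum()))


def indicator_r2(spec, params) -> pd.DataFrame:
    """Per-indicator, per-level variance explained R^2 = lam^2 psi / (lam^2 psi + theta).

    Accepts any of the five specifications; saturated levels carry no factor
    structure and are omitted.  Returns a tidy frame with columns
    (indicator, level, r2).
    """
    spec = get_spec(spec)
    values = getattr(params, "values", np.asarray(params, dtype=float))
    series = spec.parameter_vector(values).as_series()
    rows = []

    def block(prefix_lam, psi_name, prefix_theta, level):
        psi = series[psi_name]
        for lab in spec.labels:
            lam = 1.0 if lab == spec.labels[0] else series[f"{prefix_lam}[{lab}]"]
            theta = series[f"{prefix_theta}[{lab}]"]
            total = lam ** 2 * psi + theta
            if total == 0:
                raise ValueError(f"zero total variance for {lab} ({level})")
            rows.append({"indicator": lab, "level": level,
                         "r2": lam ** 2 * psi / total})

    name = spec.name
    if name == "1MLR":
        block("lambda", "psi", "theta", "overall")
    elif name == "2MLR":
        block("lambda_w", "psi_w", "theta_w", "within")
        block("lambda_b", "psi_b", "theta_b", "between")
    elif name == "2Miss":
        block("lambda", "psi_w", "theta_w", "within")
        block("lambda", "psi_b", "theta_b", "between")
    elif name == "2MaxB":
        block("lambda_w", "psi_w", "theta_w", "within")
    elif name == "2MaxW":
        block("lambda_b", "psi_b", "theta_b", "between")
    else:
        raise ValueError(f"indicator_r2 not defined for {name}")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DerivedQuantities:
    """Closed-form population quantities at one ICC setting."""

    conflated_loadings: np.ndarray
    reliability_within: float
    reliability_between: float
    reliability_onelevel: float
    r2_within: np.ndarray
    r2_between: np.ndarray
    indicator_icc: np.ndarray


def derived_quantities(pop: PopulationModel) -> DerivedQuantities:
    """Evaluate the conflation/reliability layer at the population values."""
    lw, lb = pop.within_loadings, pop.between_loadings
    tw, tb = pop.theta_within, pop.theta_between
    r2_w = lw ** 2 * pop.psi_within / (lw ** 2 * pop.psi_within + tw)
    r2_b = lb ** 2 * pop.psi_between / (lb ** 2 * pop.psi_between + tb)
    return DerivedQuantities(
        conflated_loadings=conflated_loadings(pop),
        reliability_within=composite_reliability(lw, tw, pop.psi_within),
        reliability_between=composite_reliability(lb, tb, pop.psi_between),
        reliability_onelevel=design_based_reliability(pop),
        r2_within=r2_w,
        r2_between=r2_b,
        indicator_icc=pop.indicator_icc(),
    )


def conflation_curve(pop: PopulationModel, iccs) -> pd.DataFrame:
    """Tabulate the conflation/reliability layer across an ICC grid.

    One row per (icc, indicator): the weighted-average loading prediction,
    the exact probability limit of the one-level fit, the level-specific
    and design-based composite reliabilities, and the per-level variance
    explained.
    """
    import warnings

    rows = []
    for icc in iccs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop_i = pop.with_icc(float(icc))
        lam_c = conflated_loadings(pop_i)
        d = derived_quantities(pop_i)
        pt = pseudo_true_onelevel(pop_i).as_series()
        for p, lab in enumerate(pop.labels):
            exact = 1.0 if p == 0 else pt[f"lambda[{lab}]"]
            rows.append({
                "icc": float(icc), "indicator": lab,
                "conflated": lam_c[p], "pseudo_true": exact,
                "within_truth": pop.within_loadings[p],
                "between_truth": pop.between_loadings[p],
                "r2_within": d.r2_within[p], "r2_between": d.r2_between[p],
                "indicator_icc": d.indicator_icc[p],
                "reliability_within": d.reliability_within,
                "reliability_between": d.reliability_between,
                "reliability_onelevel": d.reliability_onelevel,
            })
    return pd.DataFrame(rows)
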