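"""Monte Carlo study orchestration and criterion statistics.

Each replication is evaluated against the generating population: Wald 95%
intervals from the cluster-robust standard errors give per-parameter
coverage and empirical power; condition summaries aggregate converged,
admissible fits into mean estimates, mean SEs, coverage and power
proportions, and relative/absolute bias

    RB = 100 (mean estimate - truth) / truth,
    AB = mean of per-replication |100 (estimate - truth) / truth|,

so AB >= |RB| and noise inflates AB but not RB.  One-level fixed effects are
judged against the within-level population values (the level the
design-based analysis is meant to inform), and additionally against their
conflated pseudo-truths (the ICC-weighted loading averages).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimation
from .moments import compute_moments
from .population import PopulationModel, with_icc
from .sampling import SimulationCondition, generate_dataset
from .theory import conflated_loadings

__all__ = ["ParamEval", "ReplicationRecord", "evaluate_replication",
           "summarize_condition", "simulate_condition", "run_study"]

Z_CRIT = 1.96  # large-sample Wald critical value for CIs and significance


@dataclass(frozen=True)
class ParamEval:
    """One free parameter of one fit, judged against its population value."""

    name: str
    level: str
    kind: str
    indicator: str | None
    estimate: float
    se: float
    truth: float | None
    ci_low: float
    ci_high: float
    covered: bool | None
    significant: bool
    truth_conflated: float | None = None
    covered_conflated: bool | None = None


@dataclass(frozen=True)
class ReplicationRecord:
    """Flags, fit statistics and parameter evaluations of one fit attempt."""

    spec: str
    replicate: int
    converged: bool
    admissible: bool
    cluster_number: int
    cluster_size: int
    icc: float
    neg2loglik: float = math.nan
    chisq: float = math.nan
    df: int = 0
    scaling_factor: float = math.nan
    params: list[ParamEval] = field(default_factory=list)
    indices: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _pop_sigma_entry(pop: PopulationModel, level: str, indicator: str) -> float:
    mat = pop.sigma_between() if level == "between" else pop.sigma_within()
    labs = list(pop.labels)
    parts = indicator.split(",")
    i = labs.index(parts[0])
    j = labs.index(parts[-1])
    return float(mat[i, j])


def _truth(pop: PopulationModel, info, level: str) -> float | None:
    """Population value mapped to a free parameter at a given level.

    One-level ("overall") fixed effects are compared to the within-level
    population values.
    """
    labs = list(pop.labels)
    idx = labs.index(info.indicator.split(",")[0]) if info.indicator else None
    if info.name.startswith(("sigma", "var")):
        lev = "between" if level == "between" else "within"
        return _pop_sigma_entry(pop, lev, info.indicator)
    if info.kind == "loading":
        if level == "between":
            return float(pop.between_loadings[idx])
        return float(pop.within_loadings[idx])
    if info.kind == "factor_variance":
        return float(pop.psi_between if level == "between" else pop.psi_within)
    if info.kind == "residual_variance":
        return float(pop.theta_between[idx] if level == "between"
                     else pop.theta_within[idx])
    if info.kind == "mean":
        return float(pop.intercepts[idx])
    return None


def evaluate_replication(fit, pop: PopulationModel, replicate: int = 0,
                         condition: SimulationCondition | None = None,
                         compute_indices: bool = False) -> ReplicationRecord:
    """Judge one fit against the generating population.

    Non-converged or inadmissible fits yield a record with flags only (no
    parameter rows), which aggregation then excludes.
    """
    cn = condition.cluster_number if condition else fit.moments.G
    cs = condition.cluster_size if condition else fit.moments.n
    icc = condition.icc if condition else pop.factor_icc
    base = dict(spec=fit.spec.name, replicate=replicate,
                converged=fit.converged, admissible=fit.admissible,
                cluster_number=cn, cluster_size=cs, icc=icc)
    usable = fit.converged and fit.admissible and np.all(np.isfinite(fit.bse))
    if not usable:
        return ReplicationRecord(**base)

    conflated = conflated_loadings(pop)
    labs = list(pop.labels)
    rows: list[ParamEval] = []
    for info, est, se in zip(fit.spec.layout, fit.params.values, fit.bse):
        if se <= 0 or not np.isfinite(se):
            # nonpositive/missing SE: flag inadmissible, exclude from aggregation
            return ReplicationRecord(**{**base, "admissible": False})
        lo, hi = est - Z_CRIT * se, est + Z_CRIT * se
        significant = abs(est / se) > Z_CRIT
        levels = ("within", "between") if info.level == "both" \
            and info.kind == "loading" else (info.level,)
        for level in levels:
            truth = _truth(pop, info, level)
            tc = cc = None
            if info.kind == "loading" and info.level == "overall":
                tc = float(conflated[labs.index(info.indicator)])
                cc = bool(lo <= tc <= hi)
            rows.append(ParamEval(
                name=info.name, level=level, kind=info.kind,
                indicator=info.indicator, estimate=float(est), se=float(se),
                truth=truth, ci_low=float(lo), ci_high=float(hi),
                covered=None if truth is None else bool(lo <= truth <= hi),
                significant=bool(significant),
                truth_conflated=tc, covered_conflated=cc))

    indices = None
    if compute_indices:
        indices = fit.fit_indices().to_dict()
    return ReplicationRecord(**base, neg2loglik=float(fit.neg2loglik),
                             chisq=float(fit.chisq), df=fit.chisq_df,
                             scaling_factor=float(fit.scaling_factor),
                             params=rows, indices=indices)


def _bias(estimates: np.ndarray, truth: float | None):
    if truth is None or truth == 0 or len(estimates) == 0:
        return math.nan, math.nan
    rb = 100.0 * (estimates.mean() - truth) / truth
    ab = float(np.mean(np.abs(100.0 * (estimates - truth) / truth)))
    return float(rb), ab


def summarize_condition(records: list[ReplicationRecord],
                        pop: PopulationModel) -> dict[str, pd.DataFrame]:
    """Aggregate one condition's records into model- and parameter-level tables.

    Returns ``{"model": ..., "params": ...}``.  Aggregation uses converged,
    admissible replications; a spec with none contributes a model row with
    its convergence rate and empty statistics.
    """
    model_rows, param_rows = [], []
    for spec in dict.fromkeys(r.spec for r in records):
        attempts = [r for r in records if r.spec == spec]
        ok = [r for r in attempts if r.converged and r.admissible and r.params]
        row = {"spec": spec, "n_attempted": len(attempts),
               "n_converged": len(ok),
               "convergence_rate": len(ok) / len(attempts)}
        if ok:
            row["mean_chisq"] = float(np.mean([r.chisq for r in ok]))
            row["df"] = ok[0].df
            row["mean_scaling"] = float(np.mean([r.scaling_factor for r in ok]))
            row["mean_neg2loglik"] = float(np.mean([r.neg2loglik for r in ok]))
            if ok[0].indices is not None:
                keys = ok[0].indices.keys()
                for key in keys:
                    vals = [r.indices[key] for r in ok
                            if r.indices.get(key) is not None]
                    if vals and key not in ("df",):
                        row[f"mean_{key}"] = float(np.nanmean(vals))
        model_rows.append(row)

        if not ok:
            continue
        by_param: dict[tuple, list[ParamEval]] = {}
        for r in ok:
            for pe in r.params:
                by_param.setdefault((pe.name, pe.level), []).append(pe)
        for (name, level), evals in by_param.items():
            est = np.array([e.estimate for e in evals])
            rb, ab = _bias(est, evals[0].truth)
            prow = {
                "spec": spec, "name": name, "level": level,
                "kind": evals[0].kind, "truth": evals[0].truth,
                "mean_estimate": float(est.mean()),
                "mean_se": float(np.mean([e.se for e in evals])),
                "coverage": float(np.mean([e.covered for e in evals]))
                if evals[0].covered is not None else math.nan,
                "power": float(np.mean([e.significant for e in evals])),
                "relative_bias": rb, "absolute_bias": ab,
            }
            if evals[0].truth_conflated is not None:
                rbc, abc = _bias(est, evals[0].truth_conflated)
                prow["truth_conflated"] = evals[0].truth_conflated
                prow["relative_bias_conflated"] = rbc
                prow["absolute_bias_conflated"] = abc
                prow["coverage_conflated"] = float(
                    np.mean([e.covered_conflated for e in evals]))
            param_rows.append(prow)

    return {"model": pd.DataFrame(model_rows),
            "params": pd.DataFrame(param_rows)}


def simulate_condition(pop: PopulationModel, condition: SimulationCondition,
                       specs, compute_indices: bool = False,
                       indices_for=(), record_sink=None
                       ) -> list[ReplicationRecord]:
    """Generate, fit and evaluate every replication of one condition.

    ``pop`` must already carry the condition's ICC split.  Saturated-model
    reference quantities are computed once per dataset and shared across
    specifications.  ``indices_for`` names specs whose fit indices are
    evaluated even when ``compute_indices`` is off; ``record_sink`` is an
    optional callable receiving each record (e.g. a JSONL writer).
    """
    records = []
    for rep in range(condition.replications):
        sample = generate_dataset(pop, condition, rep)
        mom = compute_moments(sample)
        refs = {}
        for spec in specs:
            onelevel = spec == "1MLR"
            if onelevel not in refs:
                refs[onelevel] = estimation.reference_info(mom, onelevel)
            res = estimation.fit(spec, mom, labels=pop.labels,
                                 reference=refs[onelevel])
            rec = evaluate_replication(
                res, pop, replicate=rep, condition=condition,
                compute_indices=compute_indices or spec in indices_for)
            records.append(rec)
            if record_sink is not None:
                record_sink(rec)
    return records


def run_study(config, out_dir, progress: bool = True) -> dict:
    """Run the full factorial study described by a configuration.

    Writes per-replication records (``records.jsonl``), one Table-style
    parameter summary per condition (``summary_<CN>_<CS>_<ICC>.csv``),
    model-level statistics across conditions (``fit_summary.csv``) and a
    loading-bias table (``bias.csv``).  Fully reproducible from the config
    seed; estimation failures are recorded, never fatal.
    """
    import warnings

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = config.population()
    summaries = {}
    model_frames, bias_frames = [], []

    with open(out / "records.jsonl", "w") as fh:
        for cond in config.conditions():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pop_c = with_icc(pop, cond.icc)
            records = simulate_condition(
                pop_c, cond, config.specs,
                compute_indices=config.compute_indices,
                record_sink=lambda rec: fh.write(rec.to_json() + "\n"))
            tag = f"{cond.cluster_number}_{cond.cluster_size}_{cond.icc:g}"
            if progress:
                rates = ", ".join(
                    f"{s}: {sum(r.converged and r.admissible for r in records if r.spec == s)}"
                    f"/{cond.replications}" for s in config.specs)
                print(f"[condition {tag}] converged {rates}")
            summary = summarize_condition(records, pop_c)
            for key in ("model", "params"):
                summary[key].insert(0, "cluster_number", cond.cluster_number)
                summary[key].insert(1, "cluster_size", cond.cluster_size)
                summary[key].insert(2, "icc", cond.icc)
            summary["params"].to_csv(out / f"summary_{tag}.csv", index=False)
            model_frames.append(summary["model"])
            loadings = summary["params"]
            loadings = loadings[loadings["kind"] == "loading"]
            bias_frames.append(loadings)
            summaries[tag] = summary

    pd.concat(model_frames, ignore_index=True).to_csv(
        out / "fit_summary.csv", index=False)
    pd.concat(bias_frames, ignore_index=True).to_csv(
        out / "bias.csv", index=False)
    return summaries
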