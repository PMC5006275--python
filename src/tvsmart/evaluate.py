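"""Replication engine and downstream analyses.

Covers the Monte-Carlo machinery around the two estimators: per-parameter
estimate/MSE/coverage/CI-length summaries over replicated trials, simulated
and model-based (plug-in) means of the final outcome under each embedded
adaptive intervention, the power of a design to select the optimal embedded
AI, and linear trial-cost computation for time-varying versus standard
designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, EmbeddedAI, enumerate_embedded_ais
from .joint import fit_joint
from .simulate import GenParams, simulate_trial
from .tvmem import fit_tvmem

__all__ = [
    "CostSpec",
    "PowerResult",
    "ReplicationSummary",
    "simulated_ai_means",
    "estimated_ai_means",
    "run_replications",
    "trial_cost",
    "power_comparison",
    "cost_surface",
    "replicate_rng",
]

log = logging.getLogger("tvsmart")


def replicate_rng(master_seed: int, k: int) -> np.random.Generator:
    """Independent stream for replicate *k*, reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(k,))
    )


def _consistency_mask(data: pd.DataFrame, ai: EmbeddedAI, design: DesignSpec):
    a1 = data["A1"].to_numpy()
    delta = data["delta"].to_numpy()
    mask = a1 == ai.a1
    resp = delta == 1
    if ai.a2r is not None:
        mask &= np.where(resp, data["A2R"].to_numpy() == ai.a2r, True)
    mask &= np.where(~resp, data["A2NR"].to_numpy() == ai.a2nr, True)
    return mask


def simulated_ai_means(data: pd.DataFrame, design: DesignSpec) -> pd.Series:
    """Average final outcome among subjects consistent with each embedded AI.

    *data* may pool several replicates.  An AI with no consistent subjects is
    reported as missing (NaN), never as zero.
    """
    out = {}
    for ai in enumerate_embedded_ais(design):
        mask = _consistency_mask(data, ai, design)
        out[str(ai)] = float(data.loc[mask, "Y2"].mean()) if mask.any() else np.nan
    return pd.Series(out, name="simulated_mean")


def estimated_ai_means(fit, data: pd.DataFrame, design: DesignSpec) -> pd.Series:
    """Plug-in (g-computation) estimate of each embedded AI's mean final
    outcome.

    For each AI, averages the fitted final-outcome predictor over the
    subjects in that AI's first-stage arm, with the second-stage indicators
    set to the options the AI dictates for each subject's own response
    status, the subject's own ``T2``, and the random intercept at its
    population mean (0).  Responder/non-responder proportions therefore enter
    at their empirical per-arm frequencies.
    """
    p = fit.params

    def coef(name: str) -> float:
        return float(p[name]) if name in p.index else 0.0

    out = {}
    for ai in enumerate_embedded_ais(design):
        arm = data["A1"].to_numpy() == ai.a1
        if not arm.any():
            out[str(ai)] = np.nan
            continue
        sub = data.loc[arm]
        resp = (sub["delta"].to_numpy() == 1).astype(float)
        a2r = (ai.a2r if ai.a2r is not None else 0) * resp
        a2nr = ai.a2nr * (1.0 - resp)
        pred = (
            coef("beta02")
            + coef("beta12") * ai.a1
            + coef("beta22") * a2r
            + coef("beta23") * a2nr
            + coef("beta32") * sub["T2"].to_numpy()
            + coef("beta41") * ai.a1 * a2r
            + coef("beta42") * ai.a1 * a2nr
        )
        out[str(ai)] = float(pred.mean())
    return pd.Series(out, name="estimated_mean")


@dataclass
class ReplicationSummary:
    """Aggregated results of :func:`run_replications`."""

    tables: dict[str, pd.DataFrame]  # estimator -> per-parameter summary
    estimates: dict[str, pd.DataFrame]  # estimator -> raw estimates (R x params)
    ai_simulated: pd.Series
    ai_estimated: dict[str, pd.Series]
    truth: dict[str, float]
    n_replicates: int
    n_failed: dict[str, int]
    seed: int


def _fit_one(estimator: str, data, include_interactions, level, nodes, joint_kwargs):
    if estimator == "tvmem":
        return fit_tvmem(data, include_interactions, level=level)
    if estimator == "joint":
        return fit_joint(
            data, include_interactions, level=level, nodes=nodes, **joint_kwargs
        )
    raise ValueError(f"unknown estimator {estimator!r}")


def run_replications(
    design: DesignSpec,
    params: GenParams,
    R: int,
    n: int,
    estimators=("tvmem", "joint"),
    seed: int = 0,
    include_interactions: bool | None = None,
    mechanism: str = "weibull",
    level: float = 0.95,
    nodes: int = 15,
    max_failure_rate: float = 0.10,
    **joint_kwargs,
) -> ReplicationSummary:
    """Simulate *R* trials, fit each requested estimator, and aggregate
    Monte-Carlo mean estimate, MSE, CI coverage and mean CI length per
    parameter, plus per-AI simulated and estimated means.

    MSE uses the population definition (divide by R); coverage counts the
    ``level`` Wald interval containing the generating value.  Replicates
    whose fit did not converge are excluded with a logged tally; more than
    ``max_failure_rate`` failures aborts.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not estimators:
        raise ValueError("at least one estimator is required (tvmem and/or joint)")
    if include_interactions is None:
        include_interactions = params.beta41 != 0.0 or params.beta42 != 0.0
    truth = params.truth(include_interactions)
    if not design.rerandomizes_responders:
        truth.pop("beta22", None)
        truth.pop("beta41", None)

    rows: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    lows: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    highs: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    ai_est: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    n_failed = {e: 0 for e in estimators}
    ai_sum = None
    ai_count = None

    for k in range(R):
        rng = replicate_rng(seed, k)
        data = simulate_trial(design, params, n, rng, mechanism=mechanism)
        sim_means = simulated_ai_means(data, design)
        counts = pd.Series(
            {
                str(ai): int(_consistency_mask(data, ai, design).sum())
                for ai in enumerate_embedded_ais(design)
            }
        )
        contrib = sim_means.fillna(0.0) * counts
        ai_sum = contrib if ai_sum is None else ai_sum + contrib
        ai_count = counts if ai_count is None else ai_count + counts

        for est in estimators:
            try:
                fit = _fit_one(est, data, include_interactions, level, nodes, joint_kwargs)
            except Exception as exc:  # singular replicate
                log.warning("replicate %d: %s fit failed: %s", k, est, exc)
                n_failed[est] += 1
                continue
            if not fit.converged:
                log.warning("replicate %d: %s fit did not converge", k, est)
                n_failed[est] += 1
                continue
            rows[est].append(fit.params)
            lows[est].append(fit.conf_int["low"])
            highs[est].append(fit.conf_int["high"])
            ai_est[est].append(estimated_ai_means(fit, data, design))

    for est in estimators:
        if n_failed[est] > max_failure_rate * R:
            raise RuntimeError(
                f"{n_failed[est]}/{R} {est} fits failed or did not converge; "
                "the scenario appears numerically infeasible"
            )

    tables = {}
    estimates = {}
    ai_estimated = {}
    for est in estimators:
        E = pd.DataFrame(rows[est])
        L = pd.DataFrame(lows[est])
        Hi = pd.DataFrame(highs[est])
        estimates[est] = E
        recs = []
        for label, true_val in truth.items():
            if label not in E.columns:
                continue
            e = E[label].to_numpy()
            lo = L[label].to_numpy()
            hi = Hi[label].to_numpy()
            recs.append(
                {
                    "parameter": label,
                    "truth": true_val,
                    "mean_estimate": float(e.mean()),
                    "mse": float(np.mean((e - true_val) ** 2)),
                    "coverage": float(np.mean((lo <= true_val) & (true_val <= hi))),
                    "mean_ci_length": float(np.mean(hi - lo)),
                }
            )
        tables[est] = pd.DataFrame(recs).set_index("parameter")
        ai_estimated[est] = (
            pd.DataFrame(ai_est[est]).mean() if ai_est[est] else pd.Series(dtype=float)
        )

    ai_simulated = (ai_sum / ai_count.replace(0, np.nan)).rename("simulated_mean")
    return ReplicationSummary(
        tables=tables,
        estimates=estimates,
        ai_simulated=ai_simulated,
        ai_estimated=ai_estimated,
        truth=truth,
        n_replicates=R,
        n_failed=n_failed,
        seed=seed,
    )


@dataclass(frozen=True)
class CostSpec:
    """Linear cost model: ``c1``/``c2`` are the unit-time costs of medication
    and behavioral intervention; reduced intensity costs half, increased
    intensity double, and augmentation (M+B) costs ``c1 + c2``."""

    c1: float = 2.0
    c2: float = 1.0

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("unit costs must be >= 0")


def trial_cost(
    data: pd.DataFrame,
    design: DesignSpec,
    costs: CostSpec,
    stage1_at_t10: bool | None = None,
) -> float:
    """Total linear trial cost of *data* under *design*.

    Stage-1 cost accrues at the arm's unit cost for the realized duration
    ``T1`` in a time-varying design and for the full ``t10`` in a standard
    one; ``stage1_at_t10=True`` forces the standard-design stage-1 rule (used
    to price the standard analog on the same simulated subjects).  Stage-2
    cost is ``delta_t`` times the second-stage option's rate: continue at the
    arm cost, reduce at half, intensify at double, augment at ``c1 + c2``.
    """
    a1 = data["A1"].to_numpy()
    if not np.isin(a1, [-1, 1]).all():
        raise ValueError("A1 must be coded -1/+1")
    a2r = data["A2R"].to_numpy()
    a2nr = data["A2NR"].to_numpy()
    delta = data["delta"].to_numpy()
    if np.any((delta == 1) & (a2nr != 0)) or np.any((delta == 0) & (a2r != 0)):
        raise ValueError("inconsistent second-stage arm codes")
    c_arm = np.where(a1 == -1, costs.c1, costs.c2)
    if stage1_at_t10 is None:
        stage1_at_t10 = not design.time_varying
    dur1 = np.full(len(data), design.t10) if stage1_at_t10 else data["T1"].to_numpy()
    stage1 = c_arm * dur1

    rate2 = np.empty(len(data), dtype=float)
    resp = delta == 1
    # responders: continue (A2R=+1, or A2R=0 when the design never
    # re-randomizes them) at the arm rate; reduce (A2R=-1) at half rate
    rate2[resp] = np.where(a2r[resp] == -1, 0.5 * c_arm[resp], c_arm[resp])
    # non-responders: intensify (+1) at double rate; augment (-1) at c1+c2
    rate2[~resp] = np.where(
        a2nr[~resp] == 1, 2.0 * c_arm[~resp], costs.c1 + costs.c2
    )
    return float(np.sum(stage1 + rate2 * design.delta_t))


@dataclass
class PowerResult:
    """Fraction of replicates selecting the true optimal embedded AI."""

    power: dict[str, float]  # design label -> fraction
    optimal_ai: dict[str, str]
    direction: str
    n_replicates: int
    n_failed: dict[str, int]
    n_ties: dict[str, int]
    seed: int


def _select(means: pd.Series, direction: str) -> str:
    vals = means.dropna()
    if direction == "maximize":
        best = vals.max()
    else:
        best = vals.min()
    winners = vals.index[vals == best]
    return winners[0]  # deterministic AI-order tie-break


def power_comparison(
    design: DesignSpec,
    params: GenParams,
    R: int,
    n: int,
    direction: str = "maximize",
    seed: int = 0,
    estimator_timevarying: str = "joint",
    estimator_standard: str = "tvmem",
    oracle_n: int = 100_000,
    include_interactions: bool | None = None,
    level: float = 0.95,
    nodes: int = 15,
    **joint_kwargs,
) -> PowerResult:
    """Power of the time-varying design and its standard analog to select the
    true optimal embedded AI.

    The true optimal AI for each design is the extremum of the simulated AI
    means in one large oracle trial (``oracle_n`` subjects) generated at the
    true parameters.  Each replicate is then simulated, analyzed with the
    configured estimator (joint model for the time-varying design; TVMEM for
    the standard one, whose event time is constant), and the extremal
    estimated AI mean is compared with the oracle optimum.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    if include_interactions is None:
        include_interactions = params.beta41 != 0.0 or params.beta42 != 0.0
    designs = {
        "time_varying": design if design.time_varying else None,
        "standard": design.standard_analog(),
    }
    if designs["time_varying"] is None:
        raise ValueError("power_comparison expects a time-varying design")

    optimal: dict[str, str] = {}
    for j, (label, d) in enumerate(designs.items()):
        rng = replicate_rng(seed, 1_000_000 + j)
        big = simulate_trial(d, params, oracle_n, rng)
        optimal[label] = _select(simulated_ai_means(big, d), direction)

    power = {}
    n_failed = {}
    n_ties = {}
    for j, (label, d) in enumerate(designs.items()):
        estimator = estimator_timevarying if d.time_varying else estimator_standard
        correct = 0
        done = 0
        failed = 0
        ties = 0
        for k in range(R):
            rng = replicate_rng(seed, 2_000_000 * (j + 1) + k)
            data = simulate_trial(d, params, n, rng)
            try:
                fit = _fit_one(estimator, data, include_interactions, level, nodes,
                               joint_kwargs)
            except Exception as exc:
                log.warning("power %s replicate %d failed: %s", label, k, exc)
                failed += 1
                continue
            if not fit.converged:
                failed += 1
                continue
            means = estimated_ai_means(fit, data, d)
            vals = means.dropna()
            if (vals == (vals.max() if direction == "maximize" else vals.min())).sum() > 1:
                ties += 1
                log.info("power %s replicate %d: tie broken by AI order", label, k)
            done += 1
            if _select(means, direction) == optimal[label]:
                correct += 1
        if done == 0:
            raise RuntimeError(f"all {label} replicates failed")
        power[label] = correct / done
        n_failed[label] = failed
        n_ties[label] = ties

    return PowerResult(
        power=power,
        optimal_ai=optimal,
        direction=direction,
        n_replicates=R,
        n_failed=n_failed,
        n_ties=n_ties,
        seed=seed,
    )


def cost_replicates(
    design: DesignSpec,
    params: GenParams,
    costs: CostSpec,
    R: int,
    n: int,
    seed: int = 0,
    mechanism: str = "weibull",
) -> pd.DataFrame:
    """Per-replicate total cost of the time-varying design and of the
    standard pricing rule applied to the same subjects."""
    recs = []
    for k in range(R):
        rng = replicate_rng(seed, k)
        data = simulate_trial(design, params, n, rng, mechanism=mechanism)
        recs.append(
            {
                "replicate": k,
                "cost_time_varying": trial_cost(data, design, costs, stage1_at_t10=False),
                "cost_standard": trial_cost(data, design, costs, stage1_at_t10=True),
            }
        )
    return pd.DataFrame(recs)


def cost_surface(
    design: DesignSpec,
    params: GenParams,
    c1_grid,
    c2_grid,
    R: int,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean costs over a (c1, c2) grid.

    The cost is linear in the unit prices, so each replicate is simulated
    once and priced at ``(1, 0)`` and ``(0, 1)``; grid values follow by
    superposition.
    """
    basis = []
    for k in range(R):
        rng = replicate_rng(seed, k)
        data = simulate_trial(design, params, n, rng)
        row = {}
        for tag, at10 in (("tv", False), ("std", True)):
            # CostSpec validation requires >= 0; unit vectors are fine
            row[f"{tag}_u1"] = trial_cost(data, design, CostSpec(1.0, 0.0), at10)
            row[f"{tag}_u2"] = trial_cost(data, design, CostSpec(0.0, 1.0), at10)
        basis.append(row)
    base = pd.DataFrame(basis).mean()
    recs = []
    for c1 in c1_grid:
        for c2 in c2_grid:
            recs.append(
                {
                    "c1": c1,
                    "c2": c2,
                    "mean_cost_time_varying": c1 * base["tv_u1"] + c2 * base["tv_u2"],
                    "mean_cost_standard": c1 * base["std_u1"] + c2 * base["std_u2"],
                }
            )
    return pd.DataFrame(recs)
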