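"""Nonparametric bootstrap and end-to-end orchestration.

Percentile confidence intervals are built by resampling *patients* with
replacement (clones of one patient are dependent, so resampling happens
before cloning) and re-running the full estimator — including propensity /
censoring-model refits — in every resample.  One root seed spawns an
independent RNG stream per resample, so resamples are reproducible
independently of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import ccw_t2, cohort as cohort_mod, survival_t1, synthetic_claims, weighting

logger = logging.getLogger("claimstte")


@dataclass
class BootstrapPlan:
    n_resamples: int = 500
    seed: int = 0
    level: float = 95.0
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.level < 100.0:
            raise ValueError("confidence level must be in (0, 100)")


@dataclass
class BootstrapResult:
    point: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_failed: int
    estimates: pd.DataFrame = field(repr=False, default=None)


def percentile_ci(samples: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Empirical percentile interval at the given confidence level."""
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(samples, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def bootstrap(estimator: Callable[[np.ndarray], dict[str, float]],
              n_patients: int, plan: BootstrapPlan) -> BootstrapResult:
    """Percentile bootstrap of an estimator over patient resamples.

    ``estimator`` maps an index array (patient row positions, the original
    sample for the point estimate) to named scalar estimates.  Failed
    resamples (estimator exceptions) are excluded and counted; more than
    ``max_failure_fraction`` failures is an error.
    """
    point = estimator(np.arange(n_patients))
    ss = np.random.SeedSequence(plan.seed)
    streams = ss.spawn(plan.n_resamples)
    records, n_failed = [], 0
    for b in range(plan.n_resamples):
        rng = np.random.default_rng(streams[b])
        idx = rng.integers(0, n_patients, size=n_patients)
        try:
            records.append(estimator(idx))
        except Exception as exc:
            n_failed += 1
            logger.warning("bootstrap resample %d failed: %s", b, exc)
    if n_failed > plan.max_failure_fraction * plan.n_resamples:
        raise RuntimeError(f"{n_failed}/{plan.n_resamples} bootstrap resamples failed")
    est = pd.DataFrame.from_records(records)
    ci = {k: percentile_ci(est[k].to_numpy(), plan.level) for k in est.columns}
    return BootstrapResult(point=point, ci=ci, n_failed=n_failed, estimates=est)


# ---------------------------------------------------------------------------
# estimator factories (patient-index -> named estimates)
# ---------------------------------------------------------------------------

def trial1_estimator(cohort: pd.DataFrame,
                     outcome: survival_t1.OutcomeDefinition = survival_t1.COMPOSITE,
                     horizon: int = 730, truncate_pct: float = 99.0,
                     ) -> Callable[[np.ndarray], dict[str, float]]:
    """IP-weighted Kaplan-Meier risks/effects, weights refit per resample."""

    def run(idx: np.ndarray) -> dict[str, float]:
        sub = cohort.iloc[idx].reset_index(drop=True)
        ws, _ = weighting.compute_weights(sub, truncate_pct)
        curves = survival_t1.weighted_km(sub, ws, outcome, horizon)
        rt = curves["colchicine"].risk_at(horizon)
        rc = curves["NSAID"].risk_at(horizon)
        return {"risk_treated": rt, "risk_control": rc,
                "risk_difference": rt - rc,
                "risk_ratio": rt / rc if rc > 0 else float("nan")}

    return run


def trial2_estimator(aug: ccw_t2.AugmentedCohort,
                     outcome: survival_t1.OutcomeDefinition = survival_t1.COMPOSITE,
                     horizon: int = 730, truncate_pct: float = 99.0,
                     ) -> Callable[[np.ndarray], dict[str, float]]:
    """Clone-censor-weight risks/effects, re-cloned and refit per resample."""

    def run(idx: np.ndarray) -> dict[str, float]:
        sub = aug.take(idx)
        curves, _ = ccw_t2.estimate_trial2(sub, outcome, horizon, truncate_pct)
        rt = curves["long_term"].risk_at(horizon)
        rc = curves["short_term"].risk_at(horizon)
        return {"risk_treated": rt, "risk_control": rc,
                "risk_difference": rt - rc,
                "risk_ratio": rt / rc if rc > 0 else float("nan")}

    return run


# ---------------------------------------------------------------------------
# end-to-end emulation
# ---------------------------------------------------------------------------

@dataclass
class EmulationConfig:
    data_dir: str | None = None          # read an existing claims database ...
    simulate: synthetic_claims.DGPConfig | None = None   # ... or simulate one
    horizon_days: int = 730
    truncate_pct: float = 99.0
    grace_days: int = 30
    bootstrap_plan: BootstrapPlan | None = None          # None: no CIs
    subgroups: tuple[str, ...] = ("all",)
    include_truth: bool = False          # oracle columns for synthetic inputs


def run_emulation(config: EmulationConfig, out_dir: str | Path) -> dict:
    """Run both emulated trials end to end and write the report bundle."""
    from . import report as report_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        db = synthetic_claims.simulate_cohort(config.simulate)
        db.to_csv(out / "claims")
    elif config.data_dir is not None:
        db = synthetic_claims.ClaimsDatabase.from_csv(config.data_dir)
    else:
        raise ValueError("config must name a data directory or a simulation config")

    spec = cohort_mod.EligibilitySpec(study_start_day=db.study_start_day,
                                      admin_end_day=db.admin_end_day)
    cohort, attrition = cohort_mod.build_cohort(db, spec, config.horizon_days)
    cohort_mod.write_cohort(cohort, attrition, out)

    ws, model = weighting.compute_weights(cohort, config.truncate_pct)
    balance = weighting.balance_table(cohort, ws)
    balance.to_csv(out / "balance.csv", index=False)
    pd.DataFrame({"id": cohort["id"], "ps": ws.propensity,
                  "weight_raw": ws.raw_weights, "weight": ws.weights
                  }).to_csv(out / "weights.csv", index=False)

    tables = {}
    for sub in config.subgroups:
        t1 = survival_t1.run_trial1(cohort, ws, config.horizon_days, sub)
        name = "trial1_estimates" if sub == "all" else f"trial1_estimates_{sub}"
        tables[name] = t1

    aug = ccw_t2.attach_trajectories(cohort, db, config.grace_days,
                                     config.horizon_days)
    tables["trial2_estimates"] = ccw_t2.run_trial2(aug, config.horizon_days,
                                                   config.truncate_pct)

    ci_summary = {}
    if config.bootstrap_plan is not None:
        plan = config.bootstrap_plan
        res1 = bootstrap(trial1_estimator(cohort, horizon=config.horizon_days,
                                          truncate_pct=config.truncate_pct),
                         len(cohort), plan)
        res2 = bootstrap(trial2_estimator(aug, horizon=config.horizon_days,
                                          truncate_pct=config.truncate_pct),
                         len(cohort),
                         dataclasses.replace(plan, seed=plan.seed + 1))
        ci_summary = {"trial1_composite": {"point": res1.point, "ci": res1.ci,
                                           "n_failed": res1.n_failed},
                      "trial2_composite": {"point": res2.point, "ci": res2.ci,
                                           "n_failed": res2.n_failed}}

    curves1 = survival_t1.weighted_km(cohort, ws, survival_t1.COMPOSITE,
                                      config.horizon_days)
    curves2, _ = ccw_t2.estimate_trial2(aug, horizon=config.horizon_days,
                                        truncation_percentile=config.truncate_pct)
    curve_rows = []
    for trial, curves in (("trial1", curves1), ("trial2", curves2)):
        for arm, c in curves.items():
            for d, r in zip(c.days, c.risks):
                curve_rows.append({"trial": trial, "arm": arm, "day": d, "risk": r})
    tables["risk_curves"] = pd.DataFrame(curve_rows)

    truth = {}
    if config.include_truth and config.simulate is not None:
        for strategy in ("always-colchicine", "always-NSAID",
                         "colchicine-indefinite", "colchicine-90-days-then-stop"):
            t = synthetic_claims.simulate_counterfactual_risks(
                config.simulate, strategy, n_mc=100_000,
                seed=config.simulate.seed + 7, horizon=config.horizon_days)
            truth[strategy] = t.true_risk

    from . import __version__
    manifest = {
        "package": "claimstte", "version": __version__,
        "dgp_config": (dataclasses.asdict(config.simulate)
                       if config.simulate is not None else None),
        "horizon_days": config.horizon_days,
        "truncate_pct": config.truncate_pct, "grace_days": config.grace_days,
        "n_cohort": int(len(cohort)),
        "attrition": {k: int(v) for k, v in attrition.items()},
        "seed": getattr(config.simulate, "seed", None),
        "bootstrap": dataclasses.asdict(config.bootstrap_plan)
        if config.bootstrap_plan else None,
    }
    bundle = report_mod.format_estimates(tables, balance=balance,
                                         manifest=manifest, ci=ci_summary,
                                         truth=truth)
    report_mod.write_bundle(bundle, out)
    return {"tables": tables, "balance": balance, "manifest": manifest,
            "ci": ci_summary, "truth": truth}
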