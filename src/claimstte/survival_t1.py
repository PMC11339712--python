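"""Trial 1 estimators: weighted Kaplan-Meier risk curves and effect measures.

The initiator-arm contrast (colchicine vs NSAID added to urate-lowering
therapy) is analysed as the intention-to-treat analogue: patients keep
their initiation arm regardless of later discontinuation.  Risks are
1 - S(t) from a weighted product-limit estimator.  For component outcomes
that exclude death (MACE alone, MALE alone) the competing risk of death is
treated as a non-censoring event: the dead remain in the risk set,
contributing weight with no event, through the analysis horizon, so the
curve estimates cumulative incidence in the presence of death (a total
effect).  Ties on a day are resolved events-before-censorings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weighting import WeightSet

logger = logging.getLogger("claimstte")


@dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    components: tuple[str, ...]       # subset of {"MACE", "MALE", "death"}

    @property
    def death_is_competing(self) -> bool:
        return "death" not in self.components


OUTCOMES: tuple[OutcomeDefinition, ...] = (
    OutcomeDefinition("MALE, MACE, or death", ("MACE", "MALE", "death")),
    OutcomeDefinition("MALE or death", ("MALE", "death")),
    OutcomeDefinition("MACE or death", ("MACE", "death")),
    OutcomeDefinition("Death", ("death",)),
    OutcomeDefinition("MALE", ("MALE",)),
    OutcomeDefinition("MACE", ("MACE",)),
)
COMPOSITE = OUTCOMES[0]

_DAY_COLUMN = {"MACE": "mace_day", "MALE": "male_day", "death": "death_day"}


class EstimatorInputError(ValueError):
    """Negative weight or missing follow-up time."""


def event_censor_times(cohort: pd.DataFrame, outcome: OutcomeDefinition,
                       horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient (time since index, event indicator) for one outcome.

    Censoring events are disenrollment, administrative end and the horizon.
    Under the competing-risk convention the dead are retained at risk (no
    event) until the administrative censoring time.
    """
    idx = cohort["index_day"].to_numpy(dtype=float)
    admin = np.minimum(cohort["admin_censor_day"].to_numpy(dtype=float),
                       idx + horizon)
    disen = cohort["disenroll_day"].to_numpy(dtype=float)
    t_cens = np.fmin(disen, admin)          # fmin ignores NaN disenrollment
    comp_days = np.vstack([cohort[_DAY_COLUMN[c]].to_numpy(dtype=float)
                           for c in outcome.components])
    t_event = np.fmin.reduce(comp_days, axis=0) if len(comp_days) else np.full(len(idx), np.nan)

    death = cohort["death_day"].to_numpy(dtype=float)
    is_event = ~np.isnan(t_event) & (t_event <= t_cens)   # ties: event first
    time = np.where(is_event, t_event, t_cens)
    if outcome.death_is_competing:
        # death before censoring and before any component event: stay at
        # risk, event-free, until the administrative horizon
        dead_first = (~is_event) & ~np.isnan(death) & (death <= t_cens)
        time = np.where(dead_first, admin, time)
    rel = time - idx
    if np.any(~np.isfinite(rel)) or np.any(rel < 0):
        raise EstimatorInputError("missing or negative follow-up time")
    return rel, is_event.astype(bool)


@dataclass
class RiskCurve:
    """Right-continuous step function of cumulative risk; risk(0) = 0."""

    arm: str
    days: np.ndarray
    risks: np.ndarray

    def risk_at(self, day: float) -> float:
        i = np.searchsorted(self.days, day, side="right") - 1
        return float(self.risks[max(i, 0)])


def product_limit(times: np.ndarray, events: np.ndarray,
                  weights: np.ndarray, arm: str = "") -> RiskCurve:
    """Weighted product-limit estimator; events precede censorings on ties."""
    if (weights < 0).any():
        raise EstimatorInputError("negative weight")
    order = np.argsort(times, kind="stable")
    t, e, w = times[order], events[order], weights[order]
    total = w.sum()
    ev_times = np.unique(t[e])
    surv = 1.0
    days, risks = [0.0], [0.0]
    # weight removed from the risk set strictly before each event time
    removed_before = np.concatenate([[0.0], np.cumsum(w)])
    for td in ev_times:
        at_risk = total - removed_before[np.searchsorted(t, td, side="left")]
        d = w[(t == td) & e].sum()
        if at_risk <= 0:
            break
        surv *= 1.0 - d / at_risk
        days.append(float(td))
        risks.append(1.0 - surv)
    return RiskCurve(arm=arm, days=np.asarray(days), risks=np.asarray(risks))


def weighted_km(cohort: pd.DataFrame, weights: WeightSet | np.ndarray,
                outcome: OutcomeDefinition, horizon: int = 730
                ) -> dict[str, RiskCurve]:
    """Per-arm weighted Kaplan-Meier risk curves for one outcome."""
    w = weights.weights if isinstance(weights, WeightSet) else np.asarray(weights, float)
    times, events = event_censor_times(cohort, outcome, horizon)
    curves = {}
    for arm in ("colchicine", "NSAID"):
        mask = (cohort["arm"] == arm).to_numpy()
        curves[arm] = product_limit(times[mask], events[mask], w[mask], arm=arm)
    return curves


def _round_half_up(x: float, ndigits: int = 0) -> float:
    from decimal import Decimal, ROUND_HALF_UP
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EffectEstimate:
    outcome: str
    horizon: int
    risk_treated: float
    risk_control: float
    risk_difference: float
    risk_ratio: float                 # NaN when control risk is 0
    nn_label: str                     # "NNT", "NNH" or "undefined"
    nn_value: float                   # NaN when RD is 0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def number_needed(risk_difference: float) -> tuple[str, float]:
    """NNT/NNH as the half-up-rounded inverse of |risk difference|.

    Negative risk differences (treatment lowers risk) give an NNT,
    positive ones an NNH; a zero difference is flagged undefined.
    """
    if risk_difference == 0 or not np.isfinite(risk_difference):
        return "undefined", float("nan")
    label = "NNT" if risk_difference < 0 else "NNH"
    return label, _round_half_up(1.0 / abs(risk_difference))


def effect_measures(risk_treated: float, risk_control: float,
                    horizon: int = 730, outcome: str = "") -> EffectEstimate:
    """Risk difference, risk ratio and NNT/NNH from two risks."""
    rd = risk_treated - risk_control
    rr = risk_treated / risk_control if risk_control > 0 else float("nan")
    label, nn = number_needed(rd)
    return EffectEstimate(outcome=outcome, horizon=horizon,
                          risk_treated=risk_treated, risk_control=risk_control,
                          risk_difference=rd, risk_ratio=rr,
                          nn_label=label, nn_value=nn)


def run_trial1(cohort: pd.DataFrame, weights: WeightSet,
               horizon: int = 730, subgroup: str = "all") -> pd.DataFrame:
    """All six outcomes, unadjusted (unit weights) and IP-weighted.

    ``subgroup`` restricts to patients with ("cad") or without ("nocad")
    baseline coronary artery disease.
    """
    if subgroup not in ("all", "cad", "nocad"):
        raise ValueError("subgroup must be all, cad or nocad")
    mask = np.ones(len(cohort), dtype=bool)
    if subgroup == "cad":
        mask = cohort["cad"].to_numpy() == 1
    elif subgroup == "nocad":
        mask = cohort["cad"].to_numpy() == 0
    if not mask.any():
        raise ValueError(f"empty subgroup {subgroup!r}")
    sub = cohort.loc[mask].reset_index(drop=True)
    w_unit = np.ones(mask.sum())
    w_ipw = weights.weights[mask]
    rows = []
    for outcome in OUTCOMES:
        for label, w in (("unadjusted", w_unit), ("weighted", w_ipw)):
            curves = weighted_km(sub, w, outcome, horizon)
            rt = curves["colchicine"].risk_at(horizon)
            rc = curves["NSAID"].risk_at(horizon)
            est = effect_measures(rt, rc, horizon, outcome.name)
            rows.append({"outcome": outcome.name, "analysis": label,
                         "risk_treated": rt, "risk_control": rc,
                         "risk_difference": est.risk_difference,
                         "risk_ratio": est.risk_ratio,
                         "nn_label": est.nn_label, "nn_value": est.nn_value})
    return pd.DataFrame(rows)
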