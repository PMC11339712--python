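"""Synthetic insurance-claims generator with a counterfactual oracle.

Emulates the structure of linked EHR/Medicare-style claims for a cohort of
older adults with gout and peripheral artery disease (PAD) who initiate
urate-lowering therapy (ULT) together with gout-flare prophylaxis
(colchicine or an NSAID).  The generator has a known causal structure:

* baseline covariates are drawn to match the prevalences of the study
  population (comorbidity burden of a Medicare PAD cohort),
* treatment assignment is a logistic function of covariates (the
  confounding knob),
* treatment courses are sequences of 30-day dispensings that abut until a
  sampled discontinuation interval,
* gout flares are represented by steroid dispensings whose per-interval
  probability rises after prophylaxis discontinuation,
* discrete 30-day-interval hazards for MACE, MALE and death are logistic in
  covariates, current colchicine exposure, steroid use and time,
* disenrollment is an independent per-interval process.

A Monte-Carlo oracle (:func:`simulate_counterfactual_risks`) computes the
true risk under forced treatment strategies, so every estimator downstream
can be checked for parameter recovery without access to real data.

Time is integer days.  Day 0 is an arbitrary claims epoch well before the
study window so all day indices (including birth dates) are non-negative;
the study window opens at ``study_start_day``.  Follow-up intervals are
half-open 30-day blocks ``[30k, 30(k+1))`` counted from each patient's
index date.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("claimstte")

INTERVAL_DAYS = 30

# covariate names shared across the whole pipeline (order fixed)
BINARY_COVARIATES = [
    "sex_male", "race_nonwhite", "obesity", "cad", "cerebrovascular",
    "heart_failure", "afib", "ckd_1_3", "copd", "diabetes", "insulin",
    "beta_blocker", "statin", "antiplatelet", "cilostazol", "anticoagulant",
    "prior_male", "prior_mace", "rest_pain", "tissue_loss",
    "gout_encounters", "febuxostat", "prior_steroid",
]
CONTINUOUS_COVARIATES = ["age", "elixhauser", "calendar_blocks", "enrol_blocks"]

DIAGNOSIS_CATEGORIES = [
    "PAD", "gout", "CAD", "HF", "AF", "CKD1-3", "CKD4-5/ESKD", "COPD",
    "diabetes", "hypertension", "hepatic_failure", "obesity",
    "cerebrovascular", "rest_pain", "tissue_loss", "encounter",
]
DRUG_CLASSES = [
    "ULT_allopurinol", "ULT_febuxostat", "colchicine", "NSAID", "steroid",
    "statin", "beta_blocker", "antiplatelet", "anticoagulant", "cilostazol",
    "insulin", "antihypertensive_1", "antihypertensive_2", "antihypertensive_3",
]

# binary covariate -> diagnosis category emitted in the baseline lookback
_DX_FOR_COVARIATE = {
    "obesity": "obesity", "cad": "CAD", "cerebrovascular": "cerebrovascular",
    "heart_failure": "HF", "afib": "AF", "ckd_1_3": "CKD1-3", "copd": "COPD",
    "diabetes": "diabetes", "rest_pain": "rest_pain",
    "tissue_loss": "tissue_loss",
}
# binary covariate -> drug class dispensed in the baseline lookback
_RX_FOR_COVARIATE = {
    "insulin": "insulin", "beta_blocker": "beta_blocker", "statin": "statin",
    "antiplatelet": "antiplatelet", "cilostazol": "cilostazol",
    "anticoagulant": "anticoagulant", "prior_steroid": "steroid",
}

STRATEGIES = (
    "always-colchicine", "always-NSAID",
    "colchicine-90-days-then-stop", "colchicine-indefinite",
)

OUTCOME_NAMES = ("MACE", "MALE", "death")


class ConfigError(ValueError):
    """A DGP configuration field is invalid; the message names the field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CovariateModel:
    """Marginal baseline-covariate model (independent draws by default)."""

    prevalences: dict[str, float] = field(default_factory=lambda: {
        "sex_male": 0.683, "race_nonwhite": 0.092, "obesity": 0.181,
        "cad": 0.543, "cerebrovascular": 0.118, "heart_failure": 0.325,
        "afib": 0.443, "ckd_1_3": 0.164, "copd": 0.224, "diabetes": 0.521,
        "insulin": 0.144, "beta_blocker": 0.718, "statin": 0.761,
        "antiplatelet": 0.144, "cilostazol": 0.024, "anticoagulant": 0.276,
        "prior_male": 0.016, "prior_mace": 0.056, "rest_pain": 0.011,
        "tissue_loss": 0.119, "gout_encounters": 0.090, "febuxostat": 0.030,
        "prior_steroid": 0.392,
    })
    antihtn_probs: tuple[float, float, float, float] = (0.188, 0.406, 0.291, 0.115)
    age_mean: float = 77.0
    age_sd: float = 6.8
    age_min: float = 66.05
    elixhauser_mean: float = 4.9
    elixhauser_sd: float = 2.9
    elixhauser_max: int = 15
    enrol_mean_blocks: float = 60.0
    enrol_sd_blocks: float = 37.0
    enrol_min_blocks: int = 7


@dataclass
class TreatmentModel:
    """Logistic model for P(colchicine | covariates).

    Continuous covariates are centred at their configured means before the
    linear predictor is formed, so ``intercept`` is the log-odds of
    colchicine for an average patient.
    """

    intercept: float = 0.18
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "afib": 0.65, "heart_failure": 0.55, "anticoagulant": 0.65,
        "elixhauser": 0.085, "enrol_blocks": -0.004, "prior_steroid": 0.35,
        "cad": 0.25, "cerebrovascular": 0.30, "tissue_loss": 0.35,
        "prior_mace": 0.30, "gout_encounters": 0.45, "age": 0.012,
    })


@dataclass
class DurationModel:
    """Per-interval prophylaxis discontinuation probabilities.

    Geometric courses: colchicine mean ~ 270 days, NSAID ~ 150 days.
    Current steroid use (a flare) shifts the discontinuation log-odds by
    ``steroid_logit`` (negative: flares keep patients on prophylaxis).
    """

    stop_prob: dict[str, float] = field(default_factory=lambda: {
        "colchicine": 0.11, "NSAID": 0.20,
    })
    steroid_logit: float = -0.5


@dataclass
class FlareModel:
    """Per-interval steroid-use (flare proxy) probability."""

    base_prob: float = 0.05
    prior_steroid_logit: float = 0.8
    off_prophylaxis_logit: float = 0.8


@dataclass
class HazardModel:
    """Discrete per-30-day-interval hazards, logistic in covariates."""

    base_prob: dict[str, float] = field(default_factory=lambda: {
        "MACE": 0.0063, "MALE": 0.0019, "death": 0.0056,
    })
    coefficients: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "MACE": {"cad": 0.50, "afib": 0.35, "heart_failure": 0.40,
                 "diabetes": 0.25, "prior_mace": 0.70, "anticoagulant": 0.20,
                 "elixhauser": 0.06, "age": 0.020},
        "MALE": {"tissue_loss": 0.90, "rest_pain": 0.70, "prior_male": 0.80,
                 "diabetes": 0.40, "elixhauser": 0.05},
        "death": {"age": 0.055, "heart_failure": 0.50, "afib": 0.30,
                  "anticoagulant": 0.20, "elixhauser": 0.09},
    })
    steroid_logit: dict[str, float] = field(default_factory=lambda: {
        "MACE": 0.15, "MALE": 0.10, "death": 0.10,
    })
    time_trend: dict[str, float] = field(default_factory=lambda: {
        "MACE": 0.0, "MALE": 0.0, "death": 0.0,
    })


@dataclass
class CensoringModel:
    """Per-interval disenrollment probability (independent of covariates)."""

    disenroll_prob: float = 0.004


@dataclass
class DGPConfig:
    n_patients: int = 1000
    seed: int = 0
    study_start_day: int = 40000
    admin_end_day: int = 44565          # ~12.5-year study window
    max_followup_days: int = 1830       # simulate at most 5 years of follow-up
    covariates: CovariateModel = field(default_factory=CovariateModel)
    treatment: TreatmentModel = field(default_factory=TreatmentModel)
    duration: DurationModel = field(default_factory=DurationModel)
    flare: FlareModel = field(default_factory=FlareModel)
    hazard: HazardModel = field(default_factory=HazardModel)
    censoring: CensoringModel = field(default_factory=CensoringModel)
    # multiplicative hazard modifier applied while exposed to colchicine
    strategy_effect: dict[str, float] = field(default_factory=lambda: {
        "MACE": 1.0, "MALE": 1.0, "death": 1.0,
    })

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.admin_end_day <= self.study_start_day:
            raise ConfigError("admin_end_day must exceed study_start_day")
        for name, p in self.covariates.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariates.prevalences[{name}] outside [0, 1]")
        if abs(sum(self.covariates.antihtn_probs) - 1.0) > 1e-6:
            raise ConfigError("covariates.antihtn_probs must sum to 1")
        for arm, p in self.duration.stop_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"duration.stop_prob[{arm}] outside [0, 1]")
        if not 0.0 <= self.flare.base_prob <= 1.0:
            raise ConfigError("flare.base_prob outside [0, 1]")
        for o, p in self.hazard.base_prob.items():
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"hazard.base_prob[{o}] outside [0, 1)")
        if not 0.0 <= self.censoring.disenroll_prob <= 1.0:
            raise ConfigError("censoring.disenroll_prob outside [0, 1]")
        for o, m in self.strategy_effect.items():
            if m < 0:
                raise ConfigError(f"strategy_effect[{o}] must be >= 0")


def default_config(n_patients: int = 1000, seed: int = 0, **overrides) -> DGPConfig:
    """The calibrated default data-generating process.

    Defaults reproduce the study conditions: ~56% colchicine share,
    2-year composite risk around 30%, mean colchicine course ~250 days
    vs ~150 for NSAIDs, and pre-weighting imbalance (>0.10) on atrial
    fibrillation, heart failure, anticoagulation and the Elixhauser score.
    """
    cfg = DGPConfig(n_patients=n_patients, seed=seed)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def persistent_treatment_config(n_patients: int = 1000, seed: int = 0,
                                effect: dict[str, float] | None = None) -> DGPConfig:
    """Variant with no prophylaxis discontinuation.

    Under this variant every initiator stays on the assigned drug, so the
    intention-to-treat contrast between initiator arms coincides with the
    oracle always-colchicine vs always-NSAID contrast.  Used by the
    parameter-recovery and coverage harnesses.
    """
    cfg = default_config(n_patients, seed)
    cfg.duration = DurationModel(stop_prob={"colchicine": 0.0, "NSAID": 0.0},
                                 steroid_logit=0.0)
    if effect is not None:
        cfg.strategy_effect = dict(cfg.strategy_effect, **effect)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# claims database container
# ---------------------------------------------------------------------------

TABLE_COLUMNS = {
    "patients": ["id", "birth_date", "sex", "race", "elixhauser"],
    "enrollment": ["id", "start_day", "end_day"],
    "diagnoses": ["id", "day", "category"],
    "dispensings": ["id", "day", "drug_class", "days_supplied"],
    "outcomes": ["id", "day", "type"],
    "deaths": ["id", "day"],
}


@dataclass
class ClaimsDatabase:
    """Multi-table claims surrogate (patients, enrollment, diagnoses,
    dispensings, outcomes, deaths), one :class:`pandas.DataFrame` each."""

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensings: pd.DataFrame
    outcomes: pd.DataFrame
    deaths: pd.DataFrame
    study_start_day: int = 40000
    admin_end_day: int = 44565

    def validate(self) -> None:
        ids = set(self.patients["id"])
        for name in ("enrollment", "diagnoses", "dispensings", "outcomes", "deaths"):
            tab = getattr(self, name)
            if not set(tab["id"]).issubset(ids):
                raise ValueError(f"{name} references unknown patient ids")
        if (self.dispensings["days_supplied"] < 1).any():
            raise ValueError("days_supplied must be >= 1")
        if self.deaths["id"].duplicated().any():
            raise ValueError("at most one death per patient")
        for name in TABLE_COLUMNS:
            tab = getattr(self, name)
            day_cols = [c for c in tab.columns if c.endswith("day") or c == "birth_date"]
            for c in day_cols:
                if (tab[c] < 0).any():
                    raise ValueError(f"{name}.{c} contains negative day indices")
        spans = self.enrollment.sort_values(["id", "start_day"])
        prev_end = spans.groupby("id")["end_day"].shift()
        overlap = spans["start_day"] < prev_end.fillna(-1)
        if overlap.any():
            raise ValueError("overlapping enrollment spans")

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, cols in TABLE_COLUMNS.items():
            getattr(self, name)[cols].to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, in_dir: str | Path, study_start_day: int = 40000,
                 admin_end_day: int = 44565) -> "ClaimsDatabase":
        p = Path(in_dir)
        tables = {name: pd.read_csv(p / f"{name}.csv") for name in TABLE_COLUMNS}
        return cls(**tables, study_start_day=study_start_day,
                   admin_end_day=admin_end_day)


@dataclass
class SimulationTruth:
    """Monte-Carlo ground truth for one treatment strategy."""

    strategy: str
    horizon: int
    true_risk: dict[str, float]     # per outcome definition name
    mc_se: dict[str, float]
    n_mc: int


# ---------------------------------------------------------------------------
# internal draw helpers
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_covariates(cfg: DGPConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cm = cfg.covariates
    cols: dict[str, np.ndarray] = {}
    for name in BINARY_COVARIATES:
        cols[name] = (rng.random(n) < cm.prevalences[name]).astype(np.int64)
    cols["antihtn_count"] = rng.choice(4, size=n, p=list(cm.antihtn_probs))
    age = rng.normal(cm.age_mean, cm.age_sd, size=n)
    cols["age"] = np.maximum(age, cm.age_min + rng.random(n))  # truncate above 66
    elix = np.rint(rng.normal(cm.elixhauser_mean, cm.elixhauser_sd, size=n))
    cols["elixhauser"] = np.clip(elix, 0, cm.elixhauser_max).astype(np.int64)
    enrol = np.rint(rng.normal(cm.enrol_mean_blocks, cm.enrol_sd_blocks, size=n))
    cols["enrol_blocks"] = np.maximum(enrol, cm.enrol_min_blocks).astype(np.int64)
    return pd.DataFrame(cols)


def _covariate_center(cfg: DGPConfig, name: str) -> float:
    cm = cfg.covariates
    centers = {"age": cm.age_mean, "elixhauser": cm.elixhauser_mean,
               "enrol_blocks": cm.enrol_mean_blocks}
    if name in centers:
        return centers[name]
    if name == "antihtn_count":
        return float(np.dot(range(4), cm.antihtn_probs))
    return cm.prevalences.get(name, 0.0)


def _linear_predictor(cfg: DGPConfig, X: pd.DataFrame,
                      coefficients: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(X))
    for name, beta in coefficients.items():
        lp += beta * (X[name].to_numpy(dtype=float) - _covariate_center(cfg, name))
    return lp


def _hazard_prob(cfg: DGPConfig, outcome: str, X: pd.DataFrame, k: int,
                 steroid: np.ndarray, on_colchicine: np.ndarray) -> np.ndarray:
    hm = cfg.hazard
    lp = _logit(hm.base_prob[outcome]) + _linear_predictor(cfg, X, hm.coefficients[outcome])
    lp = lp + hm.steroid_logit[outcome] * steroid + hm.time_trend[outcome] * k
    p = _sigmoid(lp)
    mult = np.where(on_colchicine, cfg.strategy_effect.get(outcome, 1.0), 1.0)
    return np.clip(p * mult, 0.0, 0.999)


# ---------------------------------------------------------------------------
# observational simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: DGPConfig) -> ClaimsDatabase:
    """Generate a seeded synthetic claims database.

    Every patient is structurally eligible: gout and PAD diagnoses precede
    the ULT initiation day, the lookback window is fully enrolled, and no
    washout drug is dispensed before the index date.  Identical
    ``(config, seed)`` pairs produce identical databases.
    """
    config.validate()
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    (rng_cov, rng_cal, rng_hist, rng_treat, rng_flare, rng_stop,
     rng_haz, rng_cens, rng_off) = [np.random.default_rng(s) for s in ss.spawn(9)]

    X = _draw_covariates(config, n, rng_cov)

    span = config.admin_end_day - config.study_start_day
    index_day = config.study_start_day + rng_cal.integers(0, span, size=n)
    X["calendar_blocks"] = (index_day - config.study_start_day) // INTERVAL_DAYS
    enroll_start = index_day - X["enrol_blocks"].to_numpy() * INTERVAL_DAYS
    birth_day = index_day - np.rint(X["age"].to_numpy() * 365.25).astype(np.int64)

    # treatment assignment
    lp = config.treatment.intercept + _linear_predictor(config, X,
                                                        config.treatment.coefficients)
    p_colch = _sigmoid(lp)
    is_colch = rng_treat.random(n) < p_colch
    arm = np.where(is_colch, "colchicine", "NSAID")

    # --- baseline (lookback) claims history -------------------------------
    ids = np.arange(n, dtype=np.int64)
    dx_id, dx_day, dx_cat = [], [], []
    rx_id, rx_day, rx_class = [], [], []
    out_id, out_day, out_type = [], [], []

    def _hist_days(mask: np.ndarray, lo: int, hi: int) -> np.ndarray:
        return index_day[mask] - rng_hist.integers(lo, hi, size=int(mask.sum()))

    all_mask = np.ones(n, dtype=bool)
    for cat in ("gout", "PAD"):  # qualifying diagnoses, before the lookback
        days = _hist_days(all_mask, 184, 541)
        dx_id.append(ids); dx_day.append(days); dx_cat.append(np.full(n, cat))
    dx_id.append(ids)            # health-system-use encounter in the lookback
    dx_day.append(_hist_days(all_mask, 1, 184))
    dx_cat.append(np.full(n, "encounter"))
    for cov, cat in _DX_FOR_COVARIATE.items():
        mask = X[cov].to_numpy() == 1
        m = int(mask.sum())
        dx_id.append(ids[mask]); dx_day.append(_hist_days(mask, 1, 184))
        dx_cat.append(np.full(m, cat))
    mask = X["gout_encounters"].to_numpy() == 1   # flare encounters in lookback
    dx_id.append(ids[mask]); dx_day.append(_hist_days(mask, 1, 184))
    dx_cat.append(np.full(int(mask.sum()), "gout"))

    for cov, cls in _RX_FOR_COVARIATE.items():
        mask = X[cov].to_numpy() == 1
        rx_id.append(ids[mask]); rx_day.append(_hist_days(mask, 1, 184))
        rx_class.append(np.full(int(mask.sum()), cls))
    for j in (1, 2, 3):
        mask = X["antihtn_count"].to_numpy() >= j
        rx_id.append(ids[mask]); rx_day.append(_hist_days(mask, 1, 184))
        rx_class.append(np.full(int(mask.sum()), f"antihypertensive_{j}"))

    for cov, typ in (("prior_mace", "MACE"), ("prior_male", "MALE")):
        mask = X[cov].to_numpy() == 1
        out_id.append(ids[mask]); out_day.append(_hist_days(mask, 1, 184))
        out_type.append(np.full(int(mask.sum()), typ))

    # index-day ULT dispensing
    ult_class = np.where(X["febuxostat"].to_numpy() == 1,
                         "ULT_febuxostat", "ULT_allopurinol")
    rx_id.append(ids); rx_day.append(index_day); rx_class.append(ult_class)

    # --- follow-up --------------------------------------------------------
    end_cap = np.minimum(config.admin_end_day,
                         index_day + config.max_followup_days)
    n_intervals = int(np.ceil(config.max_followup_days / INTERVAL_DAYS))

    alive = np.ones(n, dtype=bool)
    enrolled = np.ones(n, dtype=bool)
    on_proph = np.ones(n, dtype=bool)   # still on the assigned prophylaxis
    first_mace = np.full(n, -1, dtype=np.int64)
    first_male = np.full(n, -1, dtype=np.int64)
    death_day = np.full(n, -1, dtype=np.int64)
    disenroll_day = np.full(n, -1, dtype=np.int64)

    prior_steroid = X["prior_steroid"].to_numpy() == 1
    dm, fm, cm_ = config.duration, config.flare, config.censoring

    for k in range(n_intervals):
        start = index_day + k * INTERVAL_DAYS
        active = alive & enrolled & (start < end_cap)
        if not active.any():
            break
        lo = 1 if k == 0 else 0  # follow-up days are strictly after index
        offs = rng_off.integers(lo, INTERVAL_DAYS, size=(4, n))

        # flare proxy: steroid use this interval
        lp_fl = (_logit(fm.base_prob)
                 + fm.prior_steroid_logit * prior_steroid
                 + fm.off_prophylaxis_logit * (~on_proph))
        steroid_k = active & (rng_flare.random(n) < _sigmoid(lp_fl))

        # dispensings at the interval start
        on_treat = active & on_proph
        if steroid_k.any():
            rx_id.append(ids[steroid_k]); rx_day.append(start[steroid_k])
            rx_class.append(np.full(int(steroid_k.sum()), "steroid"))
        if on_treat.any():
            rx_id.append(ids[on_treat]); rx_day.append(start[on_treat])
            rx_class.append(arm[on_treat])

        on_colch = on_treat & is_colch
        u = rng_haz.random((3, n))
        events = {}
        for i, outcome in enumerate(OUTCOME_NAMES):
            p = _hazard_prob(config, outcome, X, k, steroid_k.astype(float), on_colch)
            day = start + offs[i]
            events[outcome] = (active & (u[i] < p) & (day < end_cap), day)

        cens_hit = active & (rng_cens.random(n) < cm_.disenroll_prob)
        cens_day_k = start + offs[3]
        cens_hit &= cens_day_k < end_cap

        d_hit, d_day = events["death"]
        # observation ends at the earlier of death and disenrollment
        cut = np.full(n, np.iinfo(np.int64).max)
        cut[d_hit] = d_day[d_hit]
        both = cens_hit & (~d_hit | (cens_day_k < cut))
        cut[both] = np.minimum(cut[both], cens_day_k[both])

        for outcome, store in (("MACE", first_mace), ("MALE", first_male)):
            hit, day = events[outcome]
            hit = hit & (day <= cut) & (store < 0)
            store[hit] = day[hit]

        died = d_hit & (d_day <= cut)
        death_day[died] = d_day[died]
        alive &= ~died
        lost = cens_hit & ~died & (cens_day_k <= cut)
        disenroll_day[lost] = cens_day_k[lost]
        enrolled &= ~lost

        # discontinuation decided at interval end, effective from k+1
        lp_stop = np.where(is_colch,
                           _logit(max(dm.stop_prob["colchicine"], 1e-12)),
                           _logit(max(dm.stop_prob["NSAID"], 1e-12)))
        lp_stop = lp_stop + dm.steroid_logit * steroid_k
        zero_stop = np.where(is_colch, dm.stop_prob["colchicine"],
                             dm.stop_prob["NSAID"]) <= 0.0
        stops = on_treat & ~zero_stop & (rng_stop.random(n) < _sigmoid(lp_stop))
        on_proph &= ~stops
        on_proph &= alive & enrolled

    enroll_end = np.where(disenroll_day >= 0, disenroll_day, config.admin_end_day)

    patients = pd.DataFrame({
        "id": ids, "birth_date": birth_day,
        "sex": np.where(X["sex_male"] == 1, "M", "F"),
        "race": np.where(X["race_nonwhite"] == 1, "non-white", "white"),
        "elixhauser": X["elixhauser"].to_numpy(),
    })
    enrollment = pd.DataFrame({"id": ids, "start_day": enroll_start,
                               "end_day": enroll_end})
    diagnoses = pd.DataFrame({
        "id": np.concatenate(dx_id), "day": np.concatenate(dx_day),
        "category": np.concatenate(dx_cat),
    }).sort_values(["id", "day"], kind="stable").reset_index(drop=True)
    n_supplied = np.concatenate([np.full(len(a), INTERVAL_DAYS) for a in rx_id])
    dispensings = pd.DataFrame({
        "id": np.concatenate(rx_id), "day": np.concatenate(rx_day),
        "drug_class": np.concatenate(rx_class), "days_supplied": n_supplied,
    }).sort_values(["id", "day", "drug_class"], kind="stable").reset_index(drop=True)

    f_id, f_day, f_type = [], [], []
    for store, typ in ((first_mace, "MACE"), (first_male, "MALE")):
        mask = store >= 0
        f_id.append(ids[mask]); f_day.append(store[mask])
        f_type.append(np.full(int(mask.sum()), typ))
    if out_id:
        f_id = out_id + f_id; f_day = out_day + f_day; f_type = out_type + f_type
    outcomes = pd.DataFrame({
        "id": np.concatenate(f_id) if f_id else np.array([], dtype=np.int64),
        "day": np.concatenate(f_day) if f_day else np.array([], dtype=np.int64),
        "type": np.concatenate(f_type) if f_type else np.array([], dtype=object),
    }).sort_values(["id", "day"], kind="stable").reset_index(drop=True)
    dmask = death_day >= 0
    deaths = pd.DataFrame({"id": ids[dmask], "day": death_day[dmask]})

    db = ClaimsDatabase(patients, enrollment, diagnoses, dispensings,
                        outcomes, deaths,
                        study_start_day=config.study_start_day,
                        admin_end_day=config.admin_end_day)
    db.validate()
    return db


# ---------------------------------------------------------------------------
# counterfactual oracle
# ---------------------------------------------------------------------------

def _strategy_exposures(strategy: str, k: int) -> tuple[bool, bool]:
    """(on colchicine, on any prophylaxis) in interval k under the strategy."""
    if strategy in ("always-colchicine", "colchicine-indefinite"):
        return True, True
    if strategy == "always-NSAID":
        return False, True
    if strategy == "colchicine-90-days-then-stop":
        on = k * INTERVAL_DAYS < 90
        return on, on
    raise ValueError(f"unknown strategy {strategy!r}")


def simulate_counterfactual_risks(config: DGPConfig, strategy: str,
                                  n_mc: int = 100_000, seed: int = 0,
                                  horizon: int = 730) -> SimulationTruth:
    """Monte-Carlo ground-truth risks under a forced treatment strategy.

    Treatment follows the strategy exactly (the discontinuation process is
    switched off); covariate, flare and hazard components run unchanged and
    there is no censoring, so the returned quantities are true
    counterfactual cumulative incidences at ``horizon`` days.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    config.validate()
    ss = np.random.SeedSequence([seed, STRATEGIES.index(strategy)])
    rng_cov, rng_flare, rng_haz, rng_off = [np.random.default_rng(s)
                                            for s in ss.spawn(4)]
    X = _draw_covariates(config, n_mc, rng_cov)
    X["calendar_blocks"] = 0  # no calendar effect in the hazard model

    n_intervals = int(np.ceil(horizon / INTERVAL_DAYS))
    first = {o: np.full(n_mc, np.iinfo(np.int64).max) for o in OUTCOME_NAMES}
    alive = np.ones(n_mc, dtype=bool)
    prior_steroid = X["prior_steroid"].to_numpy() == 1
    fm = config.flare

    for k in range(n_intervals):
        on_colch_flag, on_proph_flag = _strategy_exposures(strategy, k)
        lp_fl = (_logit(fm.base_prob) + fm.prior_steroid_logit * prior_steroid
                 + fm.off_prophylaxis_logit * (not on_proph_flag))
        steroid_k = rng_flare.random(n_mc) < _sigmoid(lp_fl)
        lo = 1 if k == 0 else 0
        offs = rng_off.integers(lo, INTERVAL_DAYS, size=(3, n_mc))
        u = rng_haz.random((3, n_mc))
        on_colch = np.full(n_mc, on_colch_flag)
        death_day_k = None
        for i, outcome in enumerate(OUTCOME_NAMES):
            p = _hazard_prob(config, outcome, X, k, steroid_k.astype(float), on_colch)
            day = k * INTERVAL_DAYS + offs[i]
            hit = alive & (u[i] < p) & (day < horizon)
            if outcome == "death":
                death_day_k = np.where(hit, day, np.iinfo(np.int64).max)
                first["death"][hit & (first["death"] > day)] = day[hit & (first["death"] > day)]
            else:
                upd = hit & (first[outcome] == np.iinfo(np.int64).max)
                first[outcome][upd] = day[upd]
        # same-interval events after the death day are discarded
        for outcome in ("MACE", "MALE"):
            late = first[outcome] > death_day_k
            just_set = first[outcome] >= k * INTERVAL_DAYS
            drop = late & just_set & (first[outcome] != np.iinfo(np.int64).max)
            first[outcome][drop] = np.iinfo(np.int64).max
        alive &= death_day_k == np.iinfo(np.int64).max

    mace, male, dth = first["MACE"], first["MALE"], first["death"]
    hz = horizon
    risks = {
        "MALE, MACE, or death": np.minimum(np.minimum(mace, male), dth) <= hz,
        "MALE or death": np.minimum(male, dth) <= hz,
        "MACE or death": np.minimum(mace, dth) <= hz,
        "Death": dth <= hz,
        "MALE": male <= hz,
        "MACE": mace <= hz,
    }
    true_risk = {k: float(v.mean()) for k, v in risks.items()}
    mc_se = {k: float(np.sqrt(max(p * (1 - p), 1e-12) / n_mc))
             for k, p in true_risk.items()}
    return SimulationTruth(strategy=strategy, horizon=horizon,
                           true_risk=true_risk, mc_se=mc_se, n_mc=n_mc)


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------

def config_to_yaml(cfg: DGPConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def config_from_yaml(path: str | Path) -> DGPConfig:
    raw = yaml.safe_load(Path(path).read_text())
    sub = {"covariates": CovariateModel, "treatment": TreatmentModel,
           "duration": DurationModel, "flare": FlareModel,
           "hazard": HazardModel, "censoring": CensoringModel}
    kwargs = {}
    for key, val in raw.items():
        if key in sub:
            if key == "covariates" and "antihtn_probs" in val:
                val["antihtn_probs"] = tuple(val["antihtn_probs"])
            kwargs[key] = sub[key](**val)
        else:
            kwargs[key] = val
    cfg = DGPConfig(**kwargs)
    cfg.validate()
    return cfg
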