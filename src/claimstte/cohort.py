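"""Cohort construction: new-user identification, eligibility, baseline
covariates and follow-up ascertainment.

The design is a new-user, active-comparator cohort: patients initiating
urate-lowering therapy (ULT) after a 6-month washout of ULT, colchicine and
NSAIDs, with the prophylaxis drug dispensed alongside ULT defining the arm.
Baseline covariates are assembled from a 183-day lookback window; age, sex,
race, calendar time and enrolment duration use the full record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_claims import ClaimsDatabase, INTERVAL_DAYS

logger = logging.getLogger("claimstte")

ULT_CLASSES = ("ULT_allopurinol", "ULT_febuxostat")
WASHOUT_CLASSES = ULT_CLASSES + ("colchicine", "NSAID")
REQUIRED_DIAGNOSES = ("PAD", "gout")
EXCLUSION_DIAGNOSES = ("CKD4-5/ESKD", "hepatic_failure")

#: eligibility criteria in first-failure attribution order
CRITERIA = ("enrollment", "age", "required_dx", "encounter", "exclusion", "window")

#: fixed column order of a trial cohort table
COHORT_COLUMNS = [
    "id", "index_day", "arm",
    "age", "sex_male", "race_nonwhite", "obesity", "cad", "cerebrovascular",
    "heart_failure", "afib", "ckd_1_3", "copd", "diabetes", "insulin",
    "antihtn_count", "beta_blocker", "statin", "antiplatelet", "cilostazol",
    "anticoagulant", "prior_male", "prior_mace", "rest_pain", "tissue_loss",
    "elixhauser", "calendar_blocks", "enrol_blocks", "gout_encounters",
    "febuxostat", "prior_steroid",
    "mace_day", "male_day", "death_day", "disenroll_day", "admin_censor_day",
]


class IntegrityError(ValueError):
    """A cohort row references data absent from the claims database."""


@dataclass
class EligibilitySpec:
    min_age_years: float = 66.0           # exclusive
    lookback_days: int = 183
    pairing_window_days: int = 14
    study_start_day: int = 40000
    admin_end_day: int = 44565
    required_diagnoses: tuple[str, ...] = REQUIRED_DIAGNOSES
    exclusion_diagnoses: tuple[str, ...] = EXCLUSION_DIAGNOSES
    washout_classes: tuple[str, ...] = WASHOUT_CLASSES

    def __post_init__(self) -> None:
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be > 0")
        if self.pairing_window_days < 0:
            raise ValueError("pairing_window_days must be >= 0")


def find_initiators(db: ClaimsDatabase, spec: EligibilitySpec) -> pd.DataFrame:
    """Identify new users of ULT with an unambiguous prophylaxis arm.

    A candidate is a patient whose first ULT dispensing has no ULT,
    colchicine or NSAID dispensing in the prior ``lookback_days`` and
    exactly one of {colchicine, NSAID} dispensed within the pairing
    window.  Returns columns ``id, index_day, arm, febuxostat``.
    """
    rx = db.dispensings
    ult = rx[rx["drug_class"].isin(ULT_CLASSES)]
    if ult.empty:
        return pd.DataFrame(columns=["id", "index_day", "arm", "febuxostat"])
    first_ult = ult.sort_values(["id", "day"], kind="stable").groupby("id").first()
    first_ult = first_ult.reset_index()[["id", "day", "drug_class"]]
    first_ult = first_ult.rename(columns={"day": "index_day"})

    wash = rx[rx["drug_class"].isin(spec.washout_classes)].merge(
        first_ult[["id", "index_day"]], on="id")
    violated = wash[(wash["day"] >= wash["index_day"] - spec.lookback_days)
                    & (wash["day"] < wash["index_day"])]["id"].unique()
    cand = first_ult[~first_ult["id"].isin(violated)]

    proph = rx[rx["drug_class"].isin(("colchicine", "NSAID"))].merge(
        cand[["id", "index_day"]], on="id")
    proph = proph[(proph["day"] >= proph["index_day"])
                  & (proph["day"] <= proph["index_day"] + spec.pairing_window_days)]
    n_classes = proph.groupby("id")["drug_class"].nunique()
    unambiguous = n_classes[n_classes == 1].index
    arm = (proph[proph["id"].isin(unambiguous)]
           .groupby("id")["drug_class"].first().rename("arm"))
    out = cand.merge(arm, on="id")
    out["febuxostat"] = (out["drug_class"] == "ULT_febuxostat").astype(np.int64)
    return out[["id", "index_day", "arm", "febuxostat"]].reset_index(drop=True)


def apply_eligibility(db: ClaimsDatabase, candidates: pd.DataFrame,
                      spec: EligibilitySpec) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the trial eligibility criteria with first-failure attribution.

    Returns the eligible candidate rows and an attrition Series with the
    candidate count, one count per criterion (in :data:`CRITERIA` order)
    and the eligible count.
    """
    c = candidates.merge(db.patients[["id", "birth_date"]], on="id", how="left")
    idx = c["index_day"].to_numpy()
    look_lo = idx - spec.lookback_days

    spans = db.enrollment.merge(c[["id", "index_day"]], on="id")
    covering = spans[(spans["start_day"] <= spans["index_day"] - spec.lookback_days)
                     & (spans["end_day"] >= spans["index_day"])]["id"].unique()
    ok_enroll = c["id"].isin(covering).to_numpy()

    age = (idx - c["birth_date"].to_numpy()) / 365.25
    ok_age = age > spec.min_age_years

    dx = db.diagnoses.merge(c[["id", "index_day"]], on="id")
    have_all = np.ones(len(c), dtype=bool)
    for cat in spec.required_diagnoses:
        got = dx[(dx["category"] == cat) & (dx["day"] <= dx["index_day"])]["id"].unique()
        have_all &= c["id"].isin(got).to_numpy()
    ok_dx = have_all

    in_look = dx[(dx["day"] >= dx["index_day"] - spec.lookback_days)
                 & (dx["day"] <= dx["index_day"])]
    ok_enc = c["id"].isin(in_look["id"].unique()).to_numpy()

    excl = in_look[in_look["category"].isin(spec.exclusion_diagnoses)]["id"].unique()
    ok_excl = ~c["id"].isin(excl).to_numpy()

    ok_window = (idx >= spec.study_start_day) & (idx <= spec.admin_end_day)

    checks = {"enrollment": ok_enroll, "age": ok_age, "required_dx": ok_dx,
              "encounter": ok_enc, "exclusion": ok_excl, "window": ok_window}
    failed = np.zeros(len(c), dtype=bool)
    attrition = {"candidates": len(c)}
    for name in CRITERIA:
        newly = ~checks[name] & ~failed
        attrition[name] = int(newly.sum())
        failed |= newly
    attrition["eligible"] = int((~failed).sum())
    eligible = candidates.loc[~failed].reset_index(drop=True)
    return eligible, pd.Series(attrition)


def assemble_covariates(db: ClaimsDatabase, cohort: pd.DataFrame,
                        spec: EligibilitySpec) -> pd.DataFrame:
    """Fill the baseline covariate vector for each eligible patient.

    Lookback-window covariates use records in ``[index - lookback_days,
    index - 1]``; age, sex, race, calendar and enrolment time use the full
    record.  Raises :class:`IntegrityError` for ids absent from the
    patients table.
    """
    missing = set(cohort["id"]) - set(db.patients["id"])
    if missing:
        raise IntegrityError(f"cohort ids absent from patients table: {sorted(missing)[:5]}")
    out = cohort.copy()
    pats = db.patients.set_index("id")
    out["age"] = ((out["index_day"].to_numpy()
                   - pats.loc[out["id"], "birth_date"].to_numpy()) / 365.25)
    out["sex_male"] = (pats.loc[out["id"], "sex"].to_numpy() == "M").astype(np.int64)
    out["race_nonwhite"] = (pats.loc[out["id"], "race"].to_numpy() == "non-white").astype(np.int64)
    out["elixhauser"] = pats.loc[out["id"], "elixhauser"].to_numpy()
    out["calendar_blocks"] = (out["index_day"] - spec.study_start_day) // INTERVAL_DAYS

    first_span = (db.enrollment.sort_values(["id", "start_day"])
                  .groupby("id")["start_day"].first())
    span_start = first_span.loc[out["id"]].to_numpy()
    out["enrol_blocks"] = (out["index_day"].to_numpy() - span_start) // INTERVAL_DAYS

    def _lookback(table: pd.DataFrame) -> pd.DataFrame:
        t = table.merge(out[["id", "index_day"]], on="id")
        return t[(t["day"] >= t["index_day"] - spec.lookback_days)
                 & (t["day"] < t["index_day"])]

    dx = _lookback(db.diagnoses)
    dx_map = {"obesity": "obesity", "cad": "CAD", "cerebrovascular": "cerebrovascular",
              "heart_failure": "HF", "afib": "AF", "ckd_1_3": "CKD1-3",
              "copd": "COPD", "diabetes": "diabetes", "rest_pain": "rest_pain",
              "tissue_loss": "tissue_loss"}
    for cov, cat in dx_map.items():
        got = dx[dx["category"] == cat]["id"].unique()
        out[cov] = out["id"].isin(got).astype(np.int64)
    gout_counts = dx[dx["category"] == "gout"].groupby("id").size()
    out["gout_encounters"] = out["id"].map(gout_counts).fillna(0).astype(np.int64)

    rx = _lookback(db.dispensings)
    rx_map = {"insulin": "insulin", "beta_blocker": "beta_blocker",
              "statin": "statin", "antiplatelet": "antiplatelet",
              "cilostazol": "cilostazol", "anticoagulant": "anticoagulant",
              "prior_steroid": "steroid"}
    for cov, cls in rx_map.items():
        got = rx[rx["drug_class"] == cls]["id"].unique()
        out[cov] = out["id"].isin(got).astype(np.int64)
    anti = rx[rx["drug_class"].str.startswith("antihypertensive")]
    n_anti = anti.groupby("id")["drug_class"].nunique()
    out["antihtn_count"] = out["id"].map(n_anti).fillna(0).astype(np.int64).clip(upper=3)

    ev = _lookback(db.outcomes)
    for cov, typ in (("prior_mace", "MACE"), ("prior_male", "MALE")):
        got = ev[ev["type"] == typ]["id"].unique()
        out[cov] = out["id"].isin(got).astype(np.int64)
    return out


def ascertain_outcomes(db: ClaimsDatabase, cohort: pd.DataFrame,
                       horizon_days: int = 730) -> pd.DataFrame:
    """Record first post-index MACE/MALE, death, disenrollment and the
    administrative censoring day.

    All days are absolute; estimators convert to time since index and apply
    the analysis horizon.  The death day is carried separately so that
    component-outcome analyses can apply the competing-risk (non-censoring)
    convention.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    out = cohort.copy()
    ev = db.outcomes.merge(out[["id", "index_day"]], on="id")
    ev = ev[ev["day"] > ev["index_day"]]
    for col, typ in (("mace_day", "MACE"), ("male_day", "MALE")):
        firsts = ev[ev["type"] == typ].groupby("id")["day"].min()
        out[col] = out["id"].map(firsts)
    deaths = db.deaths.set_index("id")["day"]
    out["death_day"] = out["id"].map(deaths)
    span_end = (db.enrollment.sort_values(["id", "start_day"])
                .groupby("id")["end_day"].last())
    end = out["id"].map(span_end)
    out["disenroll_day"] = end.where(end < db.admin_end_day)
    out["admin_censor_day"] = np.minimum(out["index_day"] + horizon_days,
                                         db.admin_end_day)
    return out


def build_cohort(db: ClaimsDatabase, spec: EligibilitySpec | None = None,
                 horizon_days: int = 730) -> tuple[pd.DataFrame, pd.Series]:
    """End-to-end cohort construction; returns (cohort, attrition)."""
    if spec is None:
        spec = EligibilitySpec(study_start_day=db.study_start_day,
                               admin_end_day=db.admin_end_day)
    candidates = find_initiators(db, spec)
    eligible, attrition = apply_eligibility(db, candidates, spec)
    cohort = assemble_covariates(db, eligible, spec)
    cohort = ascertain_outcomes(db, cohort, horizon_days)
    return cohort[COHORT_COLUMNS], attrition


def write_cohort(cohort: pd.DataFrame, attrition: pd.Series,
                 out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    attrition.rename_axis("criterion").rename("count").to_csv(out / "attrition.csv")
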