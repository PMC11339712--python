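"""Shared fixtures: hand-built claims fixtures and a small simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import claimstte as c
from claimstte.synthetic_claims import ClaimsDatabase, TABLE_COLUMNS

STUDY_START = 20000
ADMIN_END = 50000


def patient_rows(pid: int, index: int = 30000, age_years: float = 72.0,
                 arm: str | None = "colchicine",
                 proph_offsets: tuple[int, ...] = (0,), supply: int = 30,
                 enroll_start: int | None = None, enroll_end: int | None = None,
                 qual_dx: bool = True, encounter: bool = True,
                 extra_dx: tuple[tuple[int, str], ...] = (),
                 extra_rx: tuple[tuple[int, str, int], ...] = (),
                 outcome_events: tuple[tuple[int, str], ...] = (),
                 death: int | None = None, elixhauser: int = 4,
                 sex: str = "M", race: str = "white") -> dict[str, list[dict]]:
    """Rows for one structurally complete patient, indexed at ``index``.

    ``proph_offsets`` are dispensing days of the arm drug relative to the
    index; ``extra_*`` take absolute days.
    """
    birth = index - round(age_years * 365.25)
    rows = {k: [] for k in TABLE_COLUMNS}
    rows["patients"].append({"id": pid, "birth_date": birth, "sex": sex,
                             "race": race, "elixhauser": elixhauser})
    rows["enrollment"].append({
        "id": pid,
        "start_day": enroll_start if enroll_start is not None else index - 900,
        "end_day": enroll_end if enroll_end is not None else ADMIN_END})
    if qual_dx:
        rows["diagnoses"] += [{"id": pid, "day": index - 200, "category": "gout"},
                              {"id": pid, "day": index - 200, "category": "PAD"}]
    if encounter:
        rows["diagnoses"].append({"id": pid, "day": index - 50,
                                  "category": "encounter"})
    for day, cat in extra_dx:
        rows["diagnoses"].append({"id": pid, "day": day, "category": cat})
    rows["dispensings"].append({"id": pid, "day": index,
                                "drug_class": "ULT_allopurinol",
                                "days_supplied": 30})
    if arm is not None:
        for off in proph_offsets:
            rows["dispensings"].append({"id": pid, "day": index + off,
                                        "drug_class": arm,
                                        "days_supplied": supply})
    for day, cls, sup in extra_rx:
        rows["dispensings"].append({"id": pid, "day": day, "drug_class": cls,
                                    "days_supplied": sup})
    for day, typ in outcome_events:
        rows["outcomes"].append({"id": pid, "day": day, "type": typ})
    if death is not None:
        rows["deaths"].append({"id": pid, "day": death})
    return rows


def build_db(*patients: dict[str, list[dict]],
             admin_end: int = ADMIN_END) -> ClaimsDatabase:
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        records = [r for p in patients for r in p[name]]
        tables[name] = pd.DataFrame(records, columns=cols)
    return ClaimsDatabase(**tables, study_start_day=STUDY_START,
                          admin_end_day=admin_end)


@pytest.fixture
def spec() -> c.EligibilitySpec:
    return c.EligibilitySpec(study_start_day=STUDY_START, admin_end_day=ADMIN_END)


@pytest.fixture(scope="session")
def sim_study():
    """A moderate simulated study shared across read-only tests."""
    cfg = c.default_config(2000, seed=42)
    db = c.simulate_cohort(cfg)
    cohort, attrition = c.build_cohort(db)
    return cfg, db, cohort, attrition


def random_survival_fixture(rng: np.random.Generator, n: int = 20,
                            index: int = 30000):
    """A small cohort DataFrame with random follow-up for KM checks."""
    patients = []
    for i in range(n):
        death = index + int(rng.integers(30, 900)) if rng.random() < 0.3 else None
        events = []
        if rng.random() < 0.4:
            events.append((index + int(rng.integers(10, 800)), "MACE"))
        if rng.random() < 0.2:
            events.append((index + int(rng.integers(10, 800)), "MALE"))
        arm = "colchicine" if i % 2 == 0 else "NSAID"
        patients.append(patient_rows(i, index=index, arm=arm,
                                     outcome_events=tuple(events), death=death))
    db = build_db(*patients)
    cohort, _ = c.build_cohort(db, c.EligibilitySpec(
        study_start_day=STUDY_START, admin_end_day=ADMIN_END))
    return cohort
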