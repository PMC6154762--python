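"""New-user cohort construction: index dates, exclusions, index-date covariates.

A candidate is any person aged <=18 with an antipsychotic fill inside the
accrual window; the index date is the earliest such fill.  Candidates are then
filtered, in a fixed order so the exclusion log is deterministic:

1. ``prior_use`` -- an antipsychotic fill in the 180-day washout before index;
2. ``insufficient_pre_enrollment`` -- enrollment does not cover
   [index-180, index];
3. ``insufficient_post_enrollment`` -- enrollment does not reach index+480
   (450 days of follow-up plus the 30-day grace);
4. ``preexisting_diabetes`` -- a *definitive* diabetes diagnosis (configured
   ICD-10 subcodes) on or before the index date;
5. ``incomplete_claims`` -- the claims-completeness interval does not cover
   [index-180, index+480].

Covariates are taken at the index date: provider type, setting, prescriber,
sex, age group, the index drug (one of the eight individually reported
antipsychotics, otherwise "others"; multiple simultaneous antipsychotics are
always "others"), antipsychotic type (FGA/SGA/both), and the summed
chlorpromazine-equivalent daily dose in categories <100 / 100-299 / 300-499 /
>=500 mg.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import ClaimsDatabase
from .config import NAMED_DRUGS, DrugDictionary, SelectionConfig

__all__ = ["ExclusionLog", "find_index_dates", "apply_new_user_criteria",
           "extract_covariates", "build_cohort", "age_group_of"]

logger = logging.getLogger(__name__)

EXCLUSION_ORDER = (
    "prior_use",
    "insufficient_pre_enrollment",
    "insufficient_post_enrollment",
    "preexisting_diabetes",
    "incomplete_claims",
)

AGE_GROUPS = ("0-3", "4-6", "7-12", "13-15", "16-18")
DOSE_CATEGORIES = ("0-99", "100-299", "300-499", ">=500")


def age_group_of(age_years: int) -> str:
    if age_years <= 3:
        return "0-3"
    if age_years <= 6:
        return "4-6"
    if age_years <= 12:
        return "7-12"
    if age_years <= 15:
        return "13-15"
    return "16-18"


def dose_category_of(cpz_mg: float) -> str:
    if cpz_mg < 100:
        return "0-99"
    if cpz_mg < 300:
        return "100-299"
    if cpz_mg < 500:
        return "300-499"
    return ">=500"


@dataclass
class ExclusionLog:
    """Per-candidate exclusion reasons (first failing rule) and their counts."""

    reasons: dict[int, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.reasons.values())
        return {r: c.get(r, 0) for r in EXCLUSION_ORDER}

    @property
    def n_excluded(self) -> int:
        return len(self.reasons)


def _person_enrollment(db: ClaimsDatabase) -> pd.DataFrame:
    """One enrollment row per person.

    Fragmented identities contribute one row per identifier pair; the rows of a
    person are merged by taking the union span (min start, max end).  Sex and
    age conflicts across a person's rows are surfaced as warnings and resolved
    by the first row (records are emitted in identity order, so this is the
    record in force at the index date for the generated data this package
    targets).
    """
    enr = db.enrollment
    rows = []
    for pid, grp in enr.groupby("person_id"):
        if grp["sex"].nunique() > 1 or grp["age_years"].nunique() > 1:
            logger.warning("person %s has conflicting sex/age across linked records", pid)
        cs = grp["complete_start"] if "complete_start" in grp else grp["enroll_start"]
        ce = grp["complete_end"] if "complete_end" in grp else grp["enroll_end"]
        rows.append((
            pid, grp["sex"].iloc[0], int(grp["age_years"].iloc[0]),
            int(grp["enroll_start"].min()), int(grp["enroll_end"].max()),
            int(cs.min()), int(ce.max()),
        ))
    return pd.DataFrame(rows, columns=[
        "person_id", "sex", "age_years", "enroll_start", "enroll_end",
        "complete_start", "complete_end",
    ])


def find_index_dates(
    db: ClaimsDatabase,
    accrual: tuple[int, int],
    drug_dict: DrugDictionary,
    max_age_years: int = 18,
) -> pd.DataFrame:
    """Earliest antipsychotic fill per person within the accrual window.

    Returns a frame of candidates (person_id, index_date) restricted to the
    study ages; persons without a qualifying fill are absent.
    """
    rx = db.prescriptions
    ap = rx[rx["drug_code"].isin(drug_dict.codes)]
    in_window = ap[(ap["fill_date"] >= accrual[0]) & (ap["fill_date"] <= accrual[1])]
    if not len(in_window):
        return pd.DataFrame(columns=["person_id", "index_date"]).astype(
            {"person_id": int, "index_date": int})
    idx = in_window.groupby("person_id")["fill_date"].min().rename("index_date")
    cand = idx.reset_index()
    enr = _person_enrollment(db)
    cand = cand.merge(enr[["person_id", "age_years"]], on="person_id", how="left")
    cand = cand[cand["age_years"].notna() & (cand["age_years"] <= max_age_years)]
    return cand[["person_id", "index_date"]].reset_index(drop=True)


def apply_new_user_criteria(
    candidates: pd.DataFrame,
    db: ClaimsDatabase,
    config: SelectionConfig,
    drug_dict: DrugDictionary,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the washout / enrollment / diabetes / completeness rules.

    Returns the retained candidates and the exclusion log; the first failing
    rule (in :data:`EXCLUSION_ORDER`) is the one recorded.
    """
    config.validate()
    enr = _person_enrollment(db).set_index("person_id")
    rx = db.prescriptions
    ap = rx[rx["drug_code"].isin(drug_dict.codes)]
    ap_by_person = {pid: grp["fill_date"].to_numpy() for pid, grp in ap.groupby("person_id")}
    dx = db.diagnoses
    diab = dx[dx["definitive"] & dx["icd10"].map(
        lambda c: any(c == p or c.startswith(p) for p in config.diabetes_codes))]
    diab_by_person = {pid: grp["date"].to_numpy() for pid, grp in diab.groupby("person_id")}

    log = ExclusionLog()
    kept = []
    for pid, index in zip(candidates["person_id"], candidates["index_date"]):
        fills = ap_by_person.get(pid, np.array([], dtype=int))
        e = enr.loc[pid]
        reason = None
        washout_lo = index - config.washout_days
        if ((fills >= washout_lo) & (fills <= index - 1)).any():
            reason = "prior_use"
        elif e["enroll_start"] > index - config.pre_enroll_days or e["enroll_end"] < index:
            reason = "insufficient_pre_enrollment"
        elif e["enroll_end"] < index + config.post_enroll_days:
            reason = "insufficient_post_enrollment"
        elif (diab_by_person.get(pid, np.array([], dtype=int)) <= index).any():
            reason = "preexisting_diabetes"
        elif (e["complete_start"] > index - config.pre_enroll_days
              or e["complete_end"] < index + config.post_enroll_days):
            reason = "incomplete_claims"
        if reason is None:
            kept.append((pid, index))
        else:
            log.reasons[int(pid)] = reason
    retained = pd.DataFrame(kept, columns=["person_id", "index_date"])
    logger.info("new-user criteria: %d candidates -> %d retained (%s)",
                len(candidates), len(retained), log.counts)
    return retained, log


def extract_covariates(
    candidates: pd.DataFrame,
    db: ClaimsDatabase,
    drug_dict: DrugDictionary,
) -> pd.DataFrame:
    """Index-date covariates for retained candidates (one row per entry)."""
    enr = _person_enrollment(db).set_index("person_id")
    rx = db.prescriptions
    ap = rx[rx["drug_code"].isin(drug_dict.codes)]
    by_person = {pid: grp for pid, grp in ap.groupby("person_id")}
    rows = []
    for pid, index in zip(candidates["person_id"], candidates["index_date"]):
        fills = by_person[pid]
        at_index = fills[fills["fill_date"] == index]
        if not len(at_index):
            raise ValueError(f"person {pid}: no antipsychotic fill on index date {index}")
        for code in at_index["drug_code"]:
            if code not in drug_dict:
                raise KeyError(f"drug code {code!r} missing from the antipsychotic dictionary")
        names = sorted({drug_dict[c].name for c in at_index["drug_code"]})
        if len(names) == 1 and names[0] in NAMED_DRUGS:
            category = names[0]
        else:
            category = "others"
        classes = set(at_index["drug_class"])
        ap_type = "both" if len(classes) > 1 else next(iter(classes))
        cpz_total = float(at_index["cpz_equiv_daily_mg"].sum())
        first = at_index.iloc[0]
        e = enr.loc[pid]
        age = int(e["age_years"])
        rows.append({
            "person_id": int(pid),
            "index_date": int(index),
            "institution_id": first["institution_id"],
            "provider_type": first["provider_type"],
            "setting": first["setting"],
            "prescriber": first["prescriber"],
            "sex": e["sex"],
            "age_years": age,
            "age_group": age_group_of(age),
            "index_drug_category": category,
            "ap_type": ap_type,
            "cpz_daily_mg": cpz_total,
            "cpz_dose_category": dose_category_of(cpz_total),
        })
    return pd.DataFrame(rows)


def build_cohort(
    db: ClaimsDatabase,
    config: SelectionConfig,
    drug_dict: DrugDictionary,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """find_index_dates -> apply_new_user_criteria -> extract_covariates."""
    candidates = find_index_dates(db, config.accrual_window, drug_dict,
                                  config.max_age_years)
    retained, log = apply_new_user_criteria(candidates, db, config, drug_dict)
    if not len(retained):
        cols = ["person_id", "index_date", "institution_id", "provider_type",
                "setting", "prescriber", "sex", "age_years", "age_group",
                "index_drug_category", "ap_type", "cpz_daily_mg", "cpz_dose_category"]
        return pd.DataFrame(columns=cols), log
    return extract_covariates(retained, db, drug_dict), log
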