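"""Synthetic claims generator with per-patient ground truth.

The generator emulates the structure of a national claims extract for
children and adolescents starting antipsychotic therapy: patients clustered
within medical institutions, dual patient identifiers with optional
fragmentation, enrollment spans, chained prescription refills with a
per-cycle discontinuation hazard, window-structured glucose/prolactin
monitoring whose probability is modified multiplicatively by covariates, and
the record types needed to exercise every exclusion rule (washout violations,
truncated enrollment, preexisting definitive diabetes).

Defaults encode reference marginals for the emulated population: boy:girl
ratio 1:0.7, realistic pediatric age-group and drug-mix distributions, a
refill continuation probability giving ~46% 90-day persistence at the
default days-supply mix, and per-window monitoring proportions in the low
range reported for metabolic monitoring of pediatric antipsychotic users.  Every patient gets
a truth record -- true index date, true discontinuation day, true per-window
monitoring indicators, and the eligibility flag with its exclusion reason --
so downstream stages can be validated exactly.

Randomness is fully determined by ``GeneratorParams.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_model import ClaimsDatabase, link_tables, write_claims
from .config import DEFAULT_DRUG_DICTIONARY, DrugDictionary
from .monitoring_metrics import PRIMARY_WINDOWS, WINDOWS
from .persistence_engine import classify_persistence, compute_discontinuation

__all__ = ["GeneratorParams", "generate_population", "fragment_identities",
           "write_dataset", "load_truth", "write_claims"]

_GLUCOSE_EMIT = ("160019410", "160010010")
_PROLACTIN_EMIT = "160032310"
_OTHER_CODE = "999999999"


@dataclass
class GeneratorParams:
    """Knobs of the synthetic population; see module docstring for defaults."""

    n_patients: int = 5000
    n_institutions: int = 750
    institution_size_dispersion: float = 1.0
    #: probability a patient is a girl (boy:girl 1:0.7)
    sex_ratio: float = 0.422
    age_group_weights: tuple[float, ...] = (0.010, 0.067, 0.303, 0.261, 0.359)
    #: drug code -> selection weight (reference drug mix; AP009 is the
    #: "others" representative)
    drug_weights: dict[str, float] = field(default_factory=lambda: {
        "AP001": 0.236, "AP002": 0.048, "AP003": 0.027, "AP004": 0.033,
        "AP005": 0.040, "AP006": 0.025, "AP007": 0.303, "AP008": 0.214,
        "AP009": 0.074,
    })
    days_supply_choices: tuple[int, ...] = (7, 14, 30)
    days_supply_weights: tuple[float, ...] = (0.25, 0.25, 0.50)
    refill_continuation_prob: float = 0.84
    #: 0 = back-to-back refills; k adds a uniform 0..k day gap per refill
    refill_gap_jitter_days: int = 0
    #: kind -> window label -> monitoring probability (reference values)
    monitoring_prob_by_window: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "glucose": {"baseline": 0.135, "m1_3": 0.108,
                        "m4_9": 0.157, "m10_15": 0.156},
            "prolactin": {"baseline": 0.006, "m1_3": 0.011,
                          "m4_9": 0.021, "m10_15": 0.019},
        })
    #: "covariate:level" -> additive log-probability effect on monitoring
    covariate_log_effects: dict[str, float] = field(default_factory=lambda: {
        "sex:girl": 0.40, "provider_type:hospital": 0.57, "setting:inpatient": 1.0,
    })
    #: expected monitoring-unrelated tests per person-year (0 isolates
    #: protocol-driven monitoring; raise to exercise contamination)
    background_test_rate: float = 0.0
    prior_user_frac: float = 0.15
    diabetes_frac: float = 0.02
    suspected_dx_frac: float = 0.02
    truncated_enrollment_frac: float = 0.05
    id_fragmentation_frac: float = 0.10
    hospital_frac: float = 0.422
    inpatient_frac: float = 0.059
    psychiatrist_frac: float = 0.551
    accrual_window: tuple[int, int] = (365, 729)
    grace_days: int = 30
    horizon: int = 450
    seed: int = 0

    def validate(self) -> None:
        probs = dict(
            sex_ratio=self.sex_ratio,
            refill_continuation_prob=self.refill_continuation_prob,
            prior_user_frac=self.prior_user_frac,
            diabetes_frac=self.diabetes_frac,
            suspected_dx_frac=self.suspected_dx_frac,
            truncated_enrollment_frac=self.truncated_enrollment_frac,
            id_fragmentation_frac=self.id_fragmentation_frac,
            hospital_frac=self.hospital_frac,
            inpatient_frac=self.inpatient_frac,
            psychiatrist_frac=self.psychiatrist_frac,
        )
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for name, w in (("age_group_weights", self.age_group_weights),
                        ("drug_weights", tuple(self.drug_weights.values())),
                        ("days_supply_weights", self.days_supply_weights)):
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(w)!r})")
            if any(x < 0 for x in w):
                raise ValueError(f"{name} has a negative weight")
        for kind, by_win in self.monitoring_prob_by_window.items():
            for win, p in by_win.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"monitoring prob {kind}/{win} out of [0,1]")
        if self.n_patients < 0 or self.n_institutions < 1:
            raise ValueError("n_patients >= 0 and n_institutions >= 1 required")
        if self.institution_size_dispersion <= 0:
            raise ValueError("institution_size_dispersion must be positive")
        if len(self.days_supply_choices) != len(self.days_supply_weights):
            raise ValueError("days_supply choices and weights must align")


_AGE_RANGES = {"0-3": (0, 3), "4-6": (4, 6), "7-12": (7, 12),
               "13-15": (13, 15), "16-18": (16, 18)}
_AGE_LABELS = tuple(_AGE_RANGES)

_TRUTH_REASONS = ("prior_use", "insufficient_pre_enrollment",
                  "insufficient_post_enrollment", "preexisting_diabetes")


def _effect_sum(effects: dict[str, float], levels: dict[str, str]) -> float:
    return sum(effects.get(f"{cov}:{lvl}", 0.0) for cov, lvl in levels.items())


def generate_population(
    params: GeneratorParams,
    drug_dict: DrugDictionary = DEFAULT_DRUG_DICTIONARY,
) -> tuple[ClaimsDatabase, pd.DataFrame]:
    """Generate a linked claims database and its truth table.

    Deterministic given ``params.seed``.  Returns the database (after
    identifier fragmentation, if configured) and one truth row per patient.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.accrual_window

    inst_ids = [f"I{j:05d}" for j in range(params.n_institutions)]
    inst_type = np.where(rng.random(params.n_institutions) < params.hospital_frac,
                         "hospital", "clinic")
    shape = 1.0 / params.institution_size_dispersion
    w = rng.gamma(shape, params.institution_size_dispersion, params.n_institutions)
    inst_p = w / w.sum()

    drug_codes = list(params.drug_weights)
    for code in drug_codes:
        if code not in drug_dict:
            raise ValueError(f"drug_weights code {code!r} absent from the drug dictionary")
    drug_p = np.array([params.drug_weights[c] for c in drug_codes], dtype=float)
    drug_p = drug_p / drug_p.sum()
    supply_p = np.array(params.days_supply_weights, dtype=float)
    supply_p = supply_p / supply_p.sum()

    enrollment, prescriptions, procedures, diagnoses, truth = [], [], [], [], []

    for i in range(params.n_patients):
        id1, id2 = f"A{i:06d}", f"B{i:06d}"
        inst = int(rng.choice(params.n_institutions, p=inst_p))
        institution_id = inst_ids[inst]
        provider_type = str(inst_type[inst])
        setting = "inpatient" if rng.random() < params.inpatient_frac else "ambulatory"
        prescriber = ("psychiatrist" if rng.random() < params.psychiatrist_frac
                      else "nonpsychiatrist")
        sex = "girl" if rng.random() < params.sex_ratio else "boy"
        age_group = str(rng.choice(_AGE_LABELS, p=params.age_group_weights))
        a_lo, a_hi = _AGE_RANGES[age_group]
        age = int(rng.integers(a_lo, a_hi + 1))

        prior_user = rng.random() < params.prior_user_frac
        truncated = rng.random() < params.truncated_enrollment_frac
        trunc_pre = bool(rng.random() < 0.5)  # draw kept unconditional for determinism
        diabetic = rng.random() < params.diabetes_frac

        if prior_user:
            # Index forced early in accrual so the washout-violating fill can
            # sit before the accrual window (otherwise it would itself be the
            # first in-window fill and the patient a clean new user).
            index = int(rng.integers(lo, lo + 91))
        else:
            index = int(rng.integers(lo, hi + 1))

        if truncated and trunc_pre:
            enroll_start = int(rng.integers(index - 179, index + 1))
            enroll_end = index + 480 + int(rng.integers(0, 101))
        elif truncated:
            enroll_start = index - 480 - int(rng.integers(0, 101))
            enroll_end = int(rng.integers(index, index + 480))
        else:
            enroll_start = index - 480 - int(rng.integers(0, 101))
            enroll_end = index + 480 + int(rng.integers(0, 101))
        enrollment.append((id1, id2, sex, age, enroll_start, enroll_end))

        drug = str(rng.choice(drug_codes, p=drug_p))
        info = drug_dict[drug]
        supply = int(rng.choice(params.days_supply_choices, p=supply_p))
        cpz = round(float(info.typical_cpz_mg * rng.lognormal(0.0, 0.5)), 1)
        rx_common = (institution_id, drug, supply, cpz, info.drug_class,
                     prescriber, setting, provider_type)

        def emit_fill(day: int, common=rx_common):
            inst_, code_, sup_, cpz_, cls_, presc_, set_, prov_ = common
            prescriptions.append((id1, id2, inst_, day, code_, sup_, cpz_,
                                  cls_, presc_, set_, prov_))

        if prior_user:
            prior_day = int(rng.integers(index - 180, lo))
            prescriptions.append((id1, id2, institution_id, prior_day, drug, 7,
                                  cpz, info.drug_class, prescriber, setting,
                                  provider_type))

        # Chained refills: continuation is Bernoulli per cycle.
        rel_fills, rel_supplies = [0], [supply]
        coverage_end = supply
        while coverage_end + params.grace_days < params.horizon + 60:
            if rng.random() >= params.refill_continuation_prob:
                break
            gap = (int(rng.integers(0, params.refill_gap_jitter_days + 1))
                   if params.refill_gap_jitter_days else 0)
            day = coverage_end + gap
            rel_fills.append(day)
            rel_supplies.append(supply)
            coverage_end = max(coverage_end, day + supply)
        for d, s in zip(rel_fills, rel_supplies):
            emit_fill(index + d)
        disc = compute_discontinuation(rel_fills, rel_supplies,
                                       params.grace_days, params.horizon)
        p90, p270, p450 = classify_persistence(disc, (90, 270, 450))

        if diabetic:
            dx_day = int(rng.integers(index - 180, index + 1))
            diagnoses.append((id1, id2, dx_day, "E11.9", True))
        if rng.random() < params.suspected_dx_frac:
            diagnoses.append((id1, id2, int(rng.integers(index - 180, index + 1)),
                              "E11.9", False))
        if rng.random() < 0.3:
            diagnoses.append((id1, id2, index, "F84.0", True))

        levels = {"sex": sex, "provider_type": provider_type, "setting": setting,
                  "prescriber": prescriber, "age_group": age_group,
                  "index_drug_category": info.name}
        eff = _effect_sum(params.covariate_log_effects, levels)
        mon: dict[tuple[str, str], bool] = {}
        for kind, by_win in params.monitoring_prob_by_window.items():
            for win in PRIMARY_WINDOWS:
                p = min(0.99, by_win.get(win, 0.0) * np.exp(eff))
                hit = rng.random() < p
                mon[(kind, win)] = bool(hit)
                if hit:
                    wdef = WINDOWS[win]
                    day = index + int(rng.integers(wdef.start_offset,
                                                   wdef.end_offset + 1))
                    if kind == "glucose":
                        code = _GLUCOSE_EMIT[0] if rng.random() < 0.7 else _GLUCOSE_EMIT[1]
                    else:
                        code = _PROLACTIN_EMIT
                    procedures.append((id1, id2, day, code))

        if params.background_test_rate > 0:
            span_years = (enroll_end - enroll_start + 1) / 365.25
            n_bg = int(rng.poisson(params.background_test_rate * span_years))
            for _ in range(n_bg):
                day = int(rng.integers(enroll_start, enroll_end + 1))
                u = rng.random()
                if u < 0.45:
                    code = _GLUCOSE_EMIT[int(rng.random() < 0.3)]
                elif u < 0.55:
                    code = _PROLACTIN_EMIT
                else:
                    code = _OTHER_CODE
                procedures.append((id1, id2, day, code))

        if prior_user:
            reason = "prior_use"
        elif truncated and trunc_pre:
            reason = "insufficient_pre_enrollment"
        elif truncated:
            reason = "insufficient_post_enrollment"
        elif diabetic:
            reason = "preexisting_diabetes"
        else:
            reason = None
        truth.append({
            "patient": i, "id1": id1, "id2": id2,
            "institution_id": institution_id,
            "sex": sex, "age_years": age, "age_group": age_group,
            "index_day": index,
            "discontinuation_day": disc,
            "persistent_90": p90, "persistent_270": p270, "persistent_450": p450,
            "eligible": reason is None,
            "exclusion_reason": reason,
            **{f"mon_{kind}_{win}": mon[(kind, win)]
               for kind in params.monitoring_prob_by_window
               for win in PRIMARY_WINDOWS},
        })

    enrollment_df = pd.DataFrame(
        enrollment, columns=["id1", "id2", "sex", "age_years",
                             "enroll_start", "enroll_end"])
    prescriptions_df = pd.DataFrame(
        prescriptions, columns=["id1", "id2", "institution_id", "fill_date",
                                "drug_code", "days_supply", "cpz_equiv_daily_mg",
                                "drug_class", "prescriber", "setting",
                                "provider_type"])
    procedures_df = pd.DataFrame(
        procedures, columns=["id1", "id2", "date", "procedure_code"])
    diagnoses_df = pd.DataFrame(
        diagnoses, columns=["id1", "id2", "date", "icd10", "definitive"])
    for df, intcols in ((enrollment_df, ("age_years", "enroll_start", "enroll_end")),
                        (prescriptions_df, ("fill_date", "days_supply")),
                        (procedures_df, ("date",)),
                        (diagnoses_df, ("date",))):
        for c in intcols:
            df[c] = df[c].astype("int64") if len(df) else pd.Series([], dtype="int64")
    if not len(diagnoses_df):
        diagnoses_df["definitive"] = diagnoses_df["definitive"].astype(bool)

    db = link_tables(enrollment_df, prescriptions_df, procedures_df, diagnoses_df)
    truth_df = pd.DataFrame(truth)
    if len(truth_df):
        truth_df["discontinuation_day"] = truth_df["discontinuation_day"].astype("Int64")

    if params.id_fragmentation_frac > 0 and params.n_patients:
        frag_seed = int(np.random.default_rng(params.seed + 1).integers(0, 2**31 - 1))
        db = fragment_identities(db, params.id_fragmentation_frac, frag_seed)
    return db, truth_df


def fragment_identities(db: ClaimsDatabase, frac: float, seed: int) -> ClaimsDatabase:
    """Split a random subset of persons across two identifier pairs.

    For each selected person a second pair is created sharing exactly one
    component with the original (which component is shared is itself random),
    and each of the person's records is independently reassigned to one of
    the two pairs.  Because one component is shared, linkage reunifies the
    pairs, so the person count is invariant.

    The Bernoulli selection draws are ``default_rng(seed).random(n_persons)``
    against ``frac``, in person-key order, so the selection can be replayed
    exactly.
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError("frac must be a probability")
    if frac == 0.0 or db.n_persons == 0:
        return db
    rng = np.random.default_rng(seed)
    person_keys = sorted(set(db.persons.pair_to_person.values()))
    selected = {pid for pid, u in zip(person_keys, rng.random(len(person_keys)))
                if u < frac}
    pair_of = {}  # person -> original (id1, id2)
    for pair, pid in db.persons.pair_to_person.items():
        pair_of.setdefault(pid, pair)
    alt_pair = {}
    for pid in selected:
        id1, id2 = pair_of[pid]
        if rng.random() < 0.5:  # share id1, fork id2
            alt_pair[pid] = (id1, id2 + "x" if id2 else "")
        else:
            alt_pair[pid] = (id1 + "x" if id1 else "", id2)

    def reassign(df: pd.DataFrame) -> pd.DataFrame:
        if not len(df):
            return df
        df = df.copy()
        id1s, id2s = df["id1"].tolist(), df["id2"].tolist()
        for j, pid in enumerate(df["person_id"]):
            if pid in alt_pair and rng.random() < 0.5:
                id1s[j], id2s[j] = alt_pair[pid]
        df["id1"], df["id2"] = id1s, id2s
        return df

    return link_tables(*(reassign(df).drop(columns=["person_id"])
                         for df in (db.enrollment, db.prescriptions,
                                    db.procedures, db.diagnoses)))


def write_dataset(db: ClaimsDatabase, truth: pd.DataFrame,
                  out_dir: Path | str) -> dict[str, Path]:
    """Write the four claims CSVs plus ``truth.json``."""
    out_dir = Path(out_dir)
    written = write_claims(db, out_dir)
    truth_path = out_dir / "truth.json"
    records = truth.to_dict(orient="records")
    for rec in records:
        d = rec.get("discontinuation_day")
        rec["discontinuation_day"] = None if pd.isna(d) else int(d)
    truth_path.write_text(json.dumps(records, indent=1, default=bool))
    written["truth"] = truth_path
    return written


def load_truth(path: Path | str) -> pd.DataFrame:
    df = pd.DataFrame(json.loads(Path(path).read_text()))
    if len(df):
        df["discontinuation_day"] = df["discontinuation_day"].astype("Int64")
    return df
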