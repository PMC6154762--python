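import numpy as np
import pandas as pd
import pytest

from rxmonitor.claims_model import load_claims
from rxmonitor.synthetic_claims import GeneratorParams, generate_population

HEADERS = {
    "enrollment": "id1,id2,sex,age_years,enroll_start,enroll_end",
    "prescriptions": ("id1,id2,institution_id,fill_date,drug_code,days_supply,"
                      "cpz_equiv_daily_mg,drug_class,prescriber,setting,provider_type"),
    "procedures": "id1,id2,date,procedure_code",
    "diagnoses": "id1,id2,date,icd10,definitive",
}


def write_fixture(tmp_path, rows: dict[str, list[str]]):
    """Write the four claims CSVs from lists of raw data lines."""
    for name, header in HEADERS.items():
        lines = [header] + rows.get(name, [])
        (tmp_path / f"{name}.csv").write_text("\n".join(lines) + "\n")
    return tmp_path


@pytest.fixture
def tiny_claims_dir(tmp_path):
    """12 data rows across the four tables; 3 distinct persons.

    Person 0 appears under two pairs sharing id1 (A1,B1)/(A1,B2); person 1 is
    (A2,B3); person 2 is (A3,B4).
    """
    rows = {
        "enrollment": [
            "A1,B1,boy,12,0,1300",
            "A1,B2,boy,12,0,1300",
            "A2,B3,girl,15,0,1300",
            "A3,B4,boy,8,0,1300",
        ],
        "prescriptions": [
            "A1,B1,I1,400,AP007,30,80.0,SGA,psychiatrist,ambulatory,clinic",
            "A1,B2,I1,430,AP007,30,80.0,SGA,psychiatrist,ambulatory,clinic",
            "A2,B3,I2,500,AP001,14,75.0,SGA,nonpsychiatrist,ambulatory,hospital",
        ],
        "procedures": [
            "A1,B1,395,160019410",
            "A2,B3,505,160032310",
            "A3,B4,600,999999999",
        ],
        "diagnoses": [
            "A2,B3,490,E11.2,true",
            "A3,B4,600,F84.0,false",
        ],
    }
    return write_fixture(tmp_path, rows)


@pytest.fixture
def tiny_db(tiny_claims_dir):
    return load_claims(tiny_claims_dir)


@pytest.fixture(scope="session")
def small_population():
    """A 600-patient generated database with truth, shared across tests."""
    params = GeneratorParams(n_patients=600, n_institutions=80, seed=20260921)
    return params, *generate_population(params)


def truth_with_person_ids(db, truth: pd.DataFrame) -> pd.DataFrame:
    """Attach linked person keys to truth rows via either identifier."""
    id_map = {}
    for (i1, i2), pid in db.persons.pair_to_person.items():
        if i1:
            id_map[i1.rstrip("x")] = pid
        if i2:
            id_map[i2.rstrip("x")] = pid
    truth = truth.copy()
    truth["person_id"] = [id_map[v] for v in truth["id1"]]
    return truth


def day_grid_discontinuation(fill_days, supplies, grace=30, horizon=450):
    """Brute-force day-by-day coverage simulation (independent oracle).

    Walk the calendar; a fill landing while coverage (plus grace) is alive
    extends coverage to the max coverage end reached.  The first day beyond
    coverage+grace is a lapse: a fill on or after that day proves the patient
    stopped and restarted, so the last covered day is the discontinuation
    date; with no further fill, a discontinuation is assigned only when the
    grace window closed before the horizon.
    """
    fills: dict[int, int] = {}
    for d, s in zip(fill_days, supplies):
        fills[d] = max(fills.get(d, 0), s)
    limit = max(fills) + max(supplies) + grace + 2
    coverage_end = None
    for day in range(0, limit):
        if coverage_end is not None and day > coverage_end + grace:
            if any(d >= day for d in fills):
                return coverage_end
            return coverage_end if coverage_end + grace < horizon else None
        if day in fills:
            coverage_end = max(coverage_end or 0, day + fills[day])
    return coverage_end if coverage_end + grace < horizon else None
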