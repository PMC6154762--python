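"""New-user selection and covariate extraction."""

import pandas as pd
import pytest

from rxmonitor.claims_model import load_claims
from rxmonitor.cohort_builder import (age_group_of, apply_new_user_criteria,
                                      build_cohort, dose_category_of,
                                      extract_covariates, find_index_dates)
from rxmonitor.config import DEFAULT_DRUG_DICTIONARY, SelectionConfig

from conftest import truth_with_person_ids, write_fixture

DD = DEFAULT_DRUG_DICTIONARY


def _db(tmp_path, prescriptions, enrollment=None, diagnoses=None):
    rows = {
        "enrollment": enrollment or ["A1,B1,boy,12,0,1300"],
        "prescriptions": prescriptions,
    }
    if diagnoses:
        rows["diagnoses"] = diagnoses
    return load_claims(write_fixture(tmp_path, rows))


RX = "{ids},I1,{day},{code},30,80.0,SGA,psychiatrist,ambulatory,clinic"


def rx(day, code="AP007", ids="A1,B1"):
    return RX.format(ids=ids, day=day, code=code)


class TestFindIndexDates:
    def test_earliest_fill_in_accrual_wins(self, tmp_path):
        db = _db(tmp_path, [rx(400), rx(500)])
        cand = find_index_dates(db, (365, 730), DD)
        assert cand["index_date"].tolist() == [400]

    def test_no_antipsychotic_fill_absent(self, tmp_path):
        db = _db(tmp_path, [rx(400, code="ZZZ")])  # not in the dictionary
        cand = find_index_dates(db, (365, 730), DD)
        assert len(cand) == 0

    def test_fill_outside_accrual_ignored(self, tmp_path):
        db = _db(tmp_path, [rx(100), rx(800)])
        cand = find_index_dates(db, (365, 730), DD)
        assert len(cand) == 0

    def test_mixed_fixture_matches_enumeration(self, tmp_path):
        enrollment = [f"A{i},B{i},boy,10,0,1300" for i in range(1, 6)]
        prescriptions = [
            rx(370, ids="A1,B1"), rx(500, ids="A1,B1"),       # index 370
            rx(900, ids="A2,B2"),                              # outside accrual
            rx(365, ids="A3,B3"),                              # boundary start
            rx(400, code="ZZZ", ids="A4,B4"),                  # unknown code
            rx(729, ids="A5,B5"),                              # boundary end
        ]
        db = _db(tmp_path, prescriptions, enrollment=enrollment)
        cand = find_index_dates(db, (365, 729), DD)
        got = dict(zip(cand["person_id"], cand["index_date"]))
        pm = db.persons
        expected = {pm.person_of("A1", "B1"): 370,
                    pm.person_of("A3", "B3"): 365,
                    pm.person_of("A5", "B5"): 729}
        assert got == expected


class TestExclusions:
    def _run(self, tmp_path, prescriptions, **kw):
        db = _db(tmp_path, prescriptions, **kw)
        cand = find_index_dates(db, (365, 730), DD)
        return apply_new_user_criteria(cand, db, SelectionConfig(), DD)

    def test_index_fill_itself_does_not_violate_washout(self, tmp_path):
        retained, log = self._run(tmp_path, [rx(370), rx(400)])
        assert len(retained) == 1 and not log.reasons

    def test_fill_30_days_before_index_is_prior_use(self, tmp_path):
        db = _db(tmp_path, [rx(340), rx(400)])
        cand = pd.DataFrame({"person_id": [0], "index_date": [400]})
        retained, log = apply_new_user_criteria(cand, db, SelectionConfig(), DD)
        assert len(retained) == 0
        assert list(log.reasons.values()) == ["prior_use"]

    def test_definitive_diabetes_on_or_before_index_excludes(self, tmp_path):
        retained, log = self._run(tmp_path, [rx(400)],
                                  diagnoses=["A1,B1,390,E11.2,true"])
        assert list(log.reasons.values()) == ["preexisting_diabetes"]

    def test_suspected_diabetes_does_not_exclude(self, tmp_path):
        retained, log = self._run(tmp_path, [rx(400)],
                                  diagnoses=["A1,B1,390,E11.2,false"])
        assert len(retained) == 1

    def test_post_index_diabetes_does_not_exclude(self, tmp_path):
        retained, log = self._run(tmp_path, [rx(400)],
                                  diagnoses=["A1,B1,401,E11.2,true"])
        assert len(retained) == 1

    def test_short_pre_enrollment_excludes(self, tmp_path):
        retained, log = self._run(tmp_path, [rx(400)],
                                  enrollment=["A1,B1,boy,12,250,1300"])
        assert list(log.reasons.values()) == ["insufficient_pre_enrollment"]

    def test_short_post_enrollment_excludes(self, tmp_path):
        retained, log = self._run(tmp_path, [rx(400)],
                                  enrollment=["A1,B1,boy,12,0,800"])
        assert list(log.reasons.values()) == ["insufficient_post_enrollment"]

    def test_incomplete_claims_interval_excludes(self, tmp_path):
        db = _db(tmp_path, [rx(400)])
        header = ("id1,id2,sex,age_years,enroll_start,enroll_end,"
                  "complete_start,complete_end")
        (tmp_path / "enrollment.csv").write_text(
            header + "\nA1,B1,boy,12,0,1300,300,1300\n")
        db = load_claims(tmp_path)
        cand = find_index_dates(db, (365, 730), DD)
        retained, log = apply_new_user_criteria(cand, db, SelectionConfig(), DD)
        assert list(log.reasons.values()) == ["incomplete_claims"]

    def test_counts_reconcile(self, small_population):
        params, db, truth = small_population
        cand = find_index_dates(db, params.accrual_window, DD)
        retained, log = apply_new_user_criteria(cand, db, SelectionConfig(), DD)
        assert len(cand) == len(retained) + log.n_excluded
        assert sum(log.counts.values()) == log.n_excluded

    def test_retained_matches_generator_truth(self, small_population):
        params, db, truth = small_population
        truth = truth_with_person_ids(db, truth)
        cohort, log = build_cohort(db, SelectionConfig(), DD)
        assert set(cohort["person_id"]) == set(truth[truth["eligible"]]["person_id"])
        t = truth.set_index("person_id")["exclusion_reason"]
        for pid, reason in log.reasons.items():
            assert t.loc[pid] == reason

    def test_no_retained_entry_violates_washout(self, small_population):
        params, db, truth = small_population
        cohort, _ = build_cohort(db, SelectionConfig(), DD)
        ap = db.prescriptions[
            db.prescriptions["drug_code"].isin(DD.codes)]
        for pid, index in zip(cohort["person_id"], cohort["index_date"]):
            fills = ap[ap["person_id"] == pid]["fill_date"]
            assert not ((fills >= index - 180) & (fills <= index - 1)).any()


class TestIncompleteClaimsHeader:
    def test_optional_columns_accepted(self, tmp_path):
        d = write_fixture(tmp_path, {"prescriptions": [rx(400)]})
        header = "id1,id2,sex,age_years,enroll_start,enroll_end,complete_start,complete_end"
        (tmp_path / "enrollment.csv").write_text(
            header + "\nA1,B1,boy,12,0,1300,0,1300\n")
        db = load_claims(d)
        assert "complete_start" in db.enrollment.columns


class TestCovariates:
    def _cov(self, tmp_path, prescriptions):
        db = _db(tmp_path, prescriptions)
        cand = pd.DataFrame({"person_id": [0], "index_date": [400]})
        return extract_covariates(cand, db, DD).iloc[0]

    def test_single_risperidone_fill(self, tmp_path):
        row = self._cov(tmp_path, [rx(400, code="AP007")])
        assert row["index_drug_category"] == "risperidone"
        assert row["ap_type"] == "SGA"

    def test_unnamed_drug_is_others(self, tmp_path):
        row = self._cov(tmp_path, [rx(400, code="AP009")])
        assert row["index_drug_category"] == "others"

    def test_simultaneous_fga_sga_is_both_and_others(self, tmp_path):
        fga = "A1,B1,I1,400,AP003,30,100.0,FGA,psychiatrist,ambulatory,clinic"
        row = self._cov(tmp_path, [rx(400, code="AP007"), fga])
        assert row["ap_type"] == "both"
        assert row["index_drug_category"] == "others"

    def test_cpz_dose_sums_across_index_fills(self, tmp_path):
        a = "A1,B1,I1,400,AP007,30,150.0,SGA,psychiatrist,ambulatory,clinic"
        b = "A1,B1,I1,400,AP004,30,100.0,SGA,psychiatrist,ambulatory,clinic"
        row = self._cov(tmp_path, [a, b])
        assert row["cpz_daily_mg"] == 250.0
        assert row["cpz_dose_category"] == "100-299"

    def test_unknown_drug_code_raises_configuration_error(self, tmp_path):
        db = _db(tmp_path, [rx(400)])
        db.prescriptions.loc[0, "drug_code"] = "MYSTERY"
        cand = pd.DataFrame({"person_id": [0], "index_date": [400]})
        # MYSTERY is filtered out as a non-antipsychotic, leaving no index fill
        with pytest.raises((KeyError, ValueError)):
            extract_covariates(cand, db, DD)


@pytest.mark.parametrize("age,group", [(0, "0-3"), (3, "0-3"), (4, "4-6"),
                                       (7, "7-12"), (13, "13-15"), (16, "16-18"),
                                       (18, "16-18")])
def test_age_groups(age, group):
    assert age_group_of(age) == group


@pytest.mark.parametrize("mg,cat", [(0, "0-99"), (99.9, "0-99"), (100, "100-299"),
                                    (299.9, "100-299"), (300, "300-499"),
                                    (500, ">=500"), (1200, ">=500")])
def test_dose_categories(mg, cat):
    assert dose_category_of(mg) == cat
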