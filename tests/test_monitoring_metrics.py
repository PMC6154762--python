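"""Windowed incidence proportions, regular monitoring, Wilson intervals."""

import math

import numpy as np
import pandas as pd
import pytest

from rxmonitor.monitoring_metrics import (WINDOWS, incidence_by_window,
                                          proportion_ci, regular_monitoring,
                                          window_of)


@pytest.mark.parametrize("day,label", [
    (-30, "baseline"), (0, "baseline"), (1, "m1_3"), (90, "m1_3"),
    (91, "m4_9"), (270, "m4_9"), (271, "m10_15"), (450, "m10_15"),
    (-31, None), (451, None),
])
def test_window_of_boundaries(day, label):
    assert window_of(day) == label


class TestWilson:
    def test_zero_numerator_low_is_zero(self):
        low, high = proportion_ci(0, 50)
        assert low == 0.0 and high > 0

    def test_full_numerator_high_is_one(self):
        low, high = proportion_ci(50, 50)
        assert high == 1.0 and low < 1

    def test_matches_direct_formula(self):
        """Independent evaluation of the Wilson score formula."""
        x, n, z = 27, 200, 1.959963984540054
        phat = x / n
        denom = 1 + z**2 / n
        center = (phat + z**2 / (2 * n)) / denom
        half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        low, high = proportion_ci(x, n)
        assert low == pytest.approx(center - half, abs=1e-12)
        assert high == pytest.approx(center + half, abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


def _frame(rows, cols):
    return pd.DataFrame(rows, columns=cols)


def _make_inputs(rng, n=50):
    """Random cohort/persistence/tests trio plus the raw ingredients."""
    persons = list(range(n))
    cohort = _frame([(p, 0) for p in persons], ["person_id", "index_date"])
    disc = [None if rng.random() < 0.3 else int(rng.integers(5, 460))
            for _ in persons]
    persistence = _frame(
        [(p, d, d is None or d >= 90, d is None or d >= 270, d is None or d >= 450)
         for p, d in zip(persons, disc)],
        ["person_id", "discontinuation_day", "persistent_90", "persistent_270",
         "persistent_450"])
    tests = []
    for p in persons:
        for _ in range(int(rng.integers(0, 4))):
            tests.append((p, int(rng.integers(-60, 500))))
    tests = _frame(tests, ["person_id", "rel_day"])
    return cohort, persistence, tests


def _enumerate_plain(cohort, persistence, tests, window, flag):
    """Loop-over-everything oracle for one window's estimate."""
    w = WINDOWS[window]
    pers = persistence.set_index("person_id")
    denom = [p for p in cohort["person_id"]
             if flag is None or bool(pers.loc[p, flag])]
    num = 0
    for p in denom:
        days = tests[tests["person_id"] == p]["rel_day"]
        if any(w.start_offset <= d <= w.end_offset for d in days):
            num += 1
    return num, len(denom)


class TestIncidenceByWindow:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        cohort, persistence, tests = _make_inputs(rng)
        estimates = {e.window: e for e in
                     incidence_by_window(cohort, persistence, tests, "glucose")}
        for window, flag in [("baseline", None), ("m1_3", "persistent_90"),
                             ("m4_9", "persistent_270"),
                             ("m10_15", "persistent_450")]:
            num, den = _enumerate_plain(cohort, persistence, tests, window, flag)
            assert (estimates[window].numerator,
                    estimates[window].denominator) == (num, den), window

    def test_index_day_test_counts_as_baseline(self):
        cohort = _frame([(0, 0)], ["person_id", "index_date"])
        persistence = _frame([(0, None, True, True, True)],
                             ["person_id", "discontinuation_day", "persistent_90",
                              "persistent_270", "persistent_450"])
        tests = _frame([(0, 0)], ["person_id", "rel_day"])
        est = {e.window: e for e in
               incidence_by_window(cohort, persistence, tests, "glucose")}
        assert est["baseline"].numerator == 1
        assert est["m1_3"].numerator == 0

    def test_nonpersistent_excluded_from_followup_window(self):
        cohort = _frame([(0, 0)], ["person_id", "index_date"])
        persistence = _frame([(0, 14, False, False, False)],
                             ["person_id", "discontinuation_day", "persistent_90",
                              "persistent_270", "persistent_450"])
        tests = _frame([(0, 50)], ["person_id", "rel_day"])
        est = {e.window: e for e in
               incidence_by_window(cohort, persistence, tests, "glucose")}
        assert est["m1_3"].denominator == 0 and est["m1_3"].numerator == 0

    def test_multiple_tests_count_once(self):
        cohort = _frame([(0, 0)], ["person_id", "index_date"])
        persistence = _frame([(0, None, True, True, True)],
                             ["person_id", "discontinuation_day", "persistent_90",
                              "persistent_270", "persistent_450"])
        tests = _frame([(0, 10), (0, 20), (0, 30)], ["person_id", "rel_day"])
        est = {e.window: e for e in
               incidence_by_window(cohort, persistence, tests, "glucose")}
        assert est["m1_3"].numerator == 1


class TestRegularMonitoring:
    def _one_person(self, test_days, disc=None):
        cohort = _frame([(0, 0)], ["person_id", "index_date"])
        persistence = _frame(
            [(0, disc, disc is None or disc >= 90, disc is None or disc >= 270,
              disc is None or disc >= 450)],
            ["person_id", "discontinuation_day", "persistent_90",
             "persistent_270", "persistent_450"])
        tests = _frame([(0, d) for d in test_days], ["person_id", "rel_day"])
        return cohort, persistence, tests

    def test_tests_in_every_window_count_everywhere(self):
        cohort, persistence, tests = self._one_person([-10, 30, 100, 300])
        four = regular_monitoring(cohort, persistence, tests, "glucose",
                                  "four_window")
        assert [e.numerator for e in four] == [1, 1, 1]
        three = regular_monitoring(cohort, persistence, tests, "glucose",
                                   "three_window")
        assert three[0].numerator == 1

    def test_baseline_gap_fails_four_window_but_not_three(self):
        cohort, persistence, tests = self._one_person([30, 100, 300])
        four = regular_monitoring(cohort, persistence, tests, "glucose",
                                  "four_window")
        assert [e.numerator for e in four] == [0, 0, 0]
        three = regular_monitoring(cohort, persistence, tests, "glucose",
                                   "three_window")
        assert three[0].numerator == 1

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        cohort, persistence, tests = _make_inputs(rng)
        pers = persistence.set_index("person_id")
        four = {e.window: e for e in
                regular_monitoring(cohort, persistence, tests, "glucose",
                                   "four_window")}
        seq = [("m1_3", "persistent_90", ["baseline", "m1_3"]),
               ("m4_9", "persistent_270", ["baseline", "m1_3", "m4_9"]),
               ("m10_15", "persistent_450",
                ["baseline", "m1_3", "m4_9", "m10_15"])]
        for window, flag, required in seq:
            num = den = 0
            for p in cohort["person_id"]:
                if not bool(pers.loc[p, flag]):
                    continue
                den += 1
                days = list(tests[tests["person_id"] == p]["rel_day"])
                if all(any(WINDOWS[w].start_offset <= d <= WINDOWS[w].end_offset
                           for d in days) for w in required):
                    num += 1
            assert (four[window].numerator, four[window].denominator) == (num, den)

    def test_regular_never_exceeds_plain(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            cohort, persistence, tests = _make_inputs(rng)
            plain = {e.window: e for e in
                     incidence_by_window(cohort, persistence, tests, "glucose")}
            four = {e.window: e for e in
                    regular_monitoring(cohort, persistence, tests, "glucose",
                                       "four_window")}
            for w, reg in four.items():
                assert reg.numerator <= plain[w].numerator
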