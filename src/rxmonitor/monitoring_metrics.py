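"""Windowed monitoring incidence proportions and regular-monitoring statistics.

Protocol windows are inclusive day intervals relative to the index date:
baseline [-30, 0], 1-3 months [1, 90], 4-9 months [91, 270], 10-15 months
[271, 450], plus a combined 0-3-month window [-30, 90] used by the
three-window regular-monitoring scheme (the baseline and 1-3-month windows
are much shorter than the later 180-day windows).

Denominators respect persistence: the baseline proportion is over the whole
cohort, while each follow-up window is restricted to users still on therapy
through that window (90- / 270- / 450-day persistent users).  A person counts
once per window regardless of how many qualifying tests fall inside it.

Regular (consecutive) monitoring at window k requires a qualifying test in
every protocol window up to and including k.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .claims_model import classify_procedure

__all__ = ["WINDOWS", "TimeWindow", "IncidenceEstimate", "window_of",
           "proportion_ci", "tests_relative", "incidence_by_window",
           "regular_monitoring"]


@dataclass(frozen=True)
class TimeWindow:
    label: str
    start_offset: int  # inclusive, days relative to index
    end_offset: int    # inclusive

    def contains(self, day: int) -> bool:
        return self.start_offset <= day <= self.end_offset


WINDOWS: dict[str, TimeWindow] = {
    "baseline": TimeWindow("baseline", -30, 0),
    "m1_3": TimeWindow("m1_3", 1, 90),
    "m4_9": TimeWindow("m4_9", 91, 270),
    "m10_15": TimeWindow("m10_15", 271, 450),
    "m0_3": TimeWindow("m0_3", -30, 90),
}

#: The four disjoint protocol windows, in temporal order.
PRIMARY_WINDOWS = ("baseline", "m1_3", "m4_9", "m10_15")

#: Persistence flag that defines each follow-up window's denominator.
DENOMINATOR_FLAG = {
    "baseline": None,            # whole cohort
    "m1_3": "persistent_90",
    "m4_9": "persistent_270",
    "m10_15": "persistent_450",
}


@dataclass(frozen=True)
class IncidenceEstimate:
    """Numerator/denominator incidence proportion with its 95% Wilson CI."""

    window: str
    kind: str
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    suppressed: bool = False


def window_of(relative_day: int) -> str | None:
    """Protocol window containing a relative day; None outside [-30, 450]."""
    for label in PRIMARY_WINDOWS:
        if WINDOWS[label].contains(relative_day):
            return label
    return None


def proportion_ci(numerator: int, denominator: int, level: float = 0.95
                  ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    low, high = proportion_confint(numerator, denominator, alpha=1 - level,
                                   method="wilson")
    # exact boundary values at x=0 / x=n (guard against float fuzz in alpha)
    if numerator == 0:
        low = 0.0
    if numerator == denominator:
        high = 1.0
    return max(0.0, float(low)), min(1.0, float(high))


def tests_relative(procedures: pd.DataFrame, cohort: pd.DataFrame,
                   kind: str) -> pd.DataFrame:
    """Qualifying tests of ``kind`` for cohort members, in days relative to
    each member's index date.  Columns: person_id, rel_day."""
    sel = procedures[procedures["procedure_code"].map(classify_procedure) == kind]
    merged = sel.merge(cohort[["person_id", "index_date"]], on="person_id", how="inner")
    merged["rel_day"] = merged["date"] - merged["index_date"]
    return merged[["person_id", "rel_day"]]


def _estimate(window: str, kind: str, num: int, den: int) -> IncidenceEstimate:
    if den == 0:
        return IncidenceEstimate(window, kind, 0, 0, float("nan"),
                                 float("nan"), float("nan"), suppressed=True)
    lo, hi = proportion_ci(num, den)
    return IncidenceEstimate(window, kind, num, den, num / den, lo, hi)


def _tested_in(tests: pd.DataFrame, window: TimeWindow) -> set[int]:
    inside = tests[(tests["rel_day"] >= window.start_offset)
                   & (tests["rel_day"] <= window.end_offset)]
    return set(inside["person_id"].tolist())


def incidence_by_window(cohort: pd.DataFrame, persistence: pd.DataFrame,
                        tests: pd.DataFrame, kind: str) -> list[IncidenceEstimate]:
    """Per-window incidence proportion of monitored patients.

    ``tests`` is the output of :func:`tests_relative` for ``kind``;
    ``persistence`` carries the persistent_90/270/450 flags per person.
    """
    pers = persistence.set_index("person_id")
    out = []
    for label in PRIMARY_WINDOWS:
        flag = DENOMINATOR_FLAG[label]
        if flag is None:
            denom = set(cohort["person_id"].tolist())
        else:
            denom = set(pers.index[pers[flag]].tolist()) & set(cohort["person_id"])
        tested = _tested_in(tests, WINDOWS[label])
        out.append(_estimate(label, kind, len(denom & tested), len(denom)))
    return out


def regular_monitoring(cohort: pd.DataFrame, persistence: pd.DataFrame,
                       tests: pd.DataFrame, kind: str,
                       scheme: str = "four_window") -> list[IncidenceEstimate]:
    """Consecutive-monitoring incidence proportions.

    four_window
        At each follow-up window k, the numerator is that window's persistent
        denominator monitored at baseline and at every window through k.
    three_window
        Among 450-day persistent users, monitored in each of the combined
        0-3-month window, 4-9 months and 10-15 months; reported as a single
        estimate labeled ``all_three``.
    """
    pers = persistence.set_index("person_id")
    cohort_ids = set(cohort["person_id"].tolist())
    if scheme == "four_window":
        out = []
        tested_cum = _tested_in(tests, WINDOWS["baseline"])
        for label in ("m1_3", "m4_9", "m10_15"):
            flag = DENOMINATOR_FLAG[label]
            denom = set(pers.index[pers[flag]].tolist()) & cohort_ids
            tested_cum = tested_cum & _tested_in(tests, WINDOWS[label])
            out.append(_estimate(label, kind, len(denom & tested_cum), len(denom)))
        return out
    if scheme == "three_window":
        denom = set(pers.index[pers["persistent_450"]].tolist()) & cohort_ids
        tested = (_tested_in(tests, WINDOWS["m0_3"])
                  & _tested_in(tests, WINDOWS["m4_9"])
                  & _tested_in(tests, WINDOWS["m10_15"]))
        return [_estimate("all_three", kind, len(denom & tested), len(denom))]
    raise ValueError(f"unknown scheme {scheme!r}")
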