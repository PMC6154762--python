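"""Aalen-Johansen cumulative incidence of first monitoring under competing risk.

Time to the initial test is followed from 30 days before the index date (the
protocol start) to 450 days after it.  Discontinuing antipsychotic therapy
(nonpersistence) is a competing event: once a patient stops, the first-test
event of interest can no longer be observed under therapy.  Patients with
neither event are censored at day 450.

For event times t_1 < t_2 < ..., with n_i at risk and d_ki cause-k events at
t_i, the overall survival is the product-limit estimator over any-cause
events, S(t) = prod_{t_i <= t} (1 - d_i/n_i), and the cause-specific
cumulative incidence is F_k(t) = sum_{t_i <= t} S(t_i-) d_ki / n_i.  The
identity S(t) + sum_k F_k(t) = 1 holds at every event time and is asserted to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ENTRY_DAY", "CENSOR_DAY", "SubjectHistory", "CifCurve",
           "build_histories", "aalen_johansen", "cif_at"]

ENTRY_DAY = -30
CENSOR_DAY = 450

CAUSES = ("monitored", "nonpersistent")


@dataclass(frozen=True)
class SubjectHistory:
    person_id: int
    event_time: int
    event_type: str  # monitored | nonpersistent | censored

    def __post_init__(self):
        if not ENTRY_DAY <= self.event_time <= CENSOR_DAY:
            raise ValueError("event_time outside the protocol span")
        if self.event_type not in CAUSES + ("censored",):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.event_type == "censored" and self.event_time != CENSOR_DAY:
            raise ValueError("censoring only occurs at the end of follow-up")


@dataclass
class CifCurve:
    """Step functions over the distinct event times (right-continuous)."""

    times: np.ndarray
    n_risk: np.ndarray
    d: dict[str, np.ndarray]
    survival: np.ndarray
    cif: dict[str, np.ndarray] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "n_risk": self.n_risk,
            **{f"d_{k}": v for k, v in self.d.items()},
            "survival": self.survival,
            **{f"cif_{k}": v for k, v in self.cif.items()},
        })


def build_histories(cohort: pd.DataFrame, persistence: pd.DataFrame,
                    tests: pd.DataFrame, tie_monitored_wins: bool = True
                    ) -> list[SubjectHistory]:
    """One history per cohort member.

    ``tests`` holds relative test days for one kind (see
    :func:`rxmonitor.monitoring_metrics.tests_relative`).  The event time is
    the earliest of: first test within [-30, 450], the discontinuation day,
    and the censoring day.  A test and a discontinuation on the same day
    resolve to ``monitored`` by default (the test was still performed).
    """
    in_span = tests[(tests["rel_day"] >= ENTRY_DAY) & (tests["rel_day"] <= CENSOR_DAY)]
    first_test = in_span.groupby("person_id")["rel_day"].min()
    disc = persistence.set_index("person_id")["discontinuation_day"]
    histories = []
    for pid in cohort["person_id"]:
        t_test = first_test.get(pid)
        d = disc.get(pid)
        t_disc = None if pd.isna(d) else int(d)
        if t_disc is not None and t_disc > CENSOR_DAY:
            t_disc = None
        if t_test is not None and (t_disc is None or t_test < t_disc
                                   or (t_test == t_disc and tie_monitored_wins)):
            histories.append(SubjectHistory(int(pid), int(t_test), "monitored"))
        elif t_disc is not None:
            histories.append(SubjectHistory(int(pid), t_disc, "nonpersistent"))
        else:
            histories.append(SubjectHistory(int(pid), CENSOR_DAY, "censored"))
    return histories


def aalen_johansen(histories: list[SubjectHistory]) -> CifCurve:
    """Cause-specific cumulative incidence curves from subject histories.

    Ties between events and end-of-follow-up censoring are handled with the
    usual convention that events at t precede censoring at t (censored
    subjects remain in the risk set at their censoring time).
    """
    if not histories:
        raise ValueError("at least one subject is required")
    times = np.array([h.event_time for h in histories])
    kinds = np.array([h.event_type for h in histories])
    event_times = np.unique(times[kinds != "censored"])
    n = len(histories)
    n_risk = np.empty(len(event_times), dtype=int)
    d = {k: np.empty(len(event_times), dtype=int) for k in CAUSES}
    surv = np.empty(len(event_times))
    cif = {k: np.empty(len(event_times)) for k in CAUSES}
    s_prev = 1.0
    f = {k: 0.0 for k in CAUSES}
    for i, t in enumerate(event_times):
        at_risk = int((times >= t).sum())
        n_risk[i] = at_risk
        d_total = 0
        for k in CAUSES:
            dk = int(((times == t) & (kinds == k)).sum())
            d[k][i] = dk
            f[k] += s_prev * dk / at_risk
            cif[k][i] = f[k]
            d_total += dk
        s_prev *= 1.0 - d_total / at_risk
        surv[i] = s_prev
    return CifCurve(event_times, n_risk, d, surv, cif)


def cif_at(curve: CifCurve, t: float, cause: str | None = None):
    """Right-continuous evaluation of the cumulative incidence at time t.

    Before the first event time the incidence is 0 by convention.  Returns a
    float for a single cause, else a dict over causes.
    """
    idx = int(np.searchsorted(curve.times, t, side="right")) - 1
    def one(k: str) -> float:
        return 0.0 if idx < 0 else float(curve.cif[k][idx])
    if cause is not None:
        return one(cause)
    return {k: one(k) for k in CAUSES}
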