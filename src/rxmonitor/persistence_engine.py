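"""Refill-gap medication persistence.

Therapy is considered continuous while each prescription's supply interval,
extended by a 30-day grace period, contains the next refill.  When a fill's
coverage lapses without a refill inside the grace window, the patient is
assigned a discontinuation date equal to the last covered day of supply.  The
canonical worked example: a single 14-day fill at the index date with no
refill in the following 30 days discontinues at day 14.

All antipsychotics are pooled, so a switch between agents simply extends
coverage; early refills extend coverage to the maximum coverage end reached
(no carry-over stockpiling of residual supply).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["PersistenceResult", "compute_discontinuation", "classify_persistence",
           "compute_persistence"]

DEFAULT_GRACE_DAYS = 30
DEFAULT_HORIZON = 450


@dataclass(frozen=True)
class PersistenceResult:
    """Discontinuation day (relative to index; None = continued through the
    horizon) and the persistent-user flags at each horizon."""

    person_id: int
    discontinuation_day: int | None
    persistent_90: bool
    persistent_270: bool
    persistent_450: bool


def compute_discontinuation(
    fill_days: Sequence[int],
    days_supply: Sequence[int],
    grace_days: int = DEFAULT_GRACE_DAYS,
    horizon: int = DEFAULT_HORIZON,
) -> int | None:
    """Walk a patient's fills and return the discontinuation day, or None.

    Parameters
    ----------
    fill_days
        Fill dates relative to the index date, sorted ascending; the first
        fill must be at day 0 (it defines the index).
    days_supply
        Days of supply per fill, aligned with ``fill_days``.
    grace_days
        Allowance added to the end of coverage before a lapse is declared.
        A refill exactly at ``coverage_end + grace_days`` still continues
        therapy (inclusive boundary).
    horizon
        Follow-up length in days.  If coverage plus grace reaches the horizon
        the patient is persistent throughout and None is returned.

    Notes
    -----
    Coverage end is the running maximum of ``fill_day + days_supply`` over the
    fills processed so far.  Same-day duplicate fills contribute once, with
    the longest supply (the max already guarantees this).
    """
    if len(fill_days) != len(days_supply):
        raise ValueError("fill_days and days_supply must align")
    if not len(fill_days):
        raise ValueError("at least one fill is required")
    if any(b < a for a, b in zip(fill_days, fill_days[1:])):
        raise ValueError("fills must be sorted by fill date")
    if fill_days[0] != 0:
        raise ValueError("first fill must be at relative day 0 (the index date)")

    coverage_end = fill_days[0] + days_supply[0]
    for day, supply in zip(fill_days[1:], days_supply[1:]):
        if day > coverage_end + grace_days:
            return coverage_end
        coverage_end = max(coverage_end, day + supply)
    if coverage_end + grace_days < horizon:
        return coverage_end
    return None


def classify_persistence(
    discontinuation_day: int | None,
    horizons: Sequence[int] = (90, 270, 450),
) -> tuple[bool, ...]:
    """Persistent at horizon H iff therapy continued at least H days after the
    index date (discontinuing exactly at H counts)."""
    return tuple(
        discontinuation_day is None or discontinuation_day >= h for h in horizons
    )


def compute_persistence(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    antipsychotic_codes: frozenset[str] | set[str],
    grace_days: int = DEFAULT_GRACE_DAYS,
    horizon: int = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Persistence results for every cohort entry.

    ``cohort`` needs ``person_id`` and ``index_date``; fills are restricted to
    antipsychotic codes on or after each person's index date.
    """
    rx = prescriptions[prescriptions["drug_code"].isin(antipsychotic_codes)]
    rx = rx.sort_values(["person_id", "fill_date"], kind="stable")
    by_person = {pid: grp for pid, grp in rx.groupby("person_id")}
    rows = []
    for pid, index_date in zip(cohort["person_id"], cohort["index_date"]):
        grp = by_person.get(pid)
        if grp is None:
            raise ValueError(f"cohort person {pid} has no antipsychotic fills")
        sel = grp[grp["fill_date"] >= index_date]
        days = (sel["fill_date"] - index_date).tolist()
        supplies = sel["days_supply"].tolist()
        disc = compute_discontinuation(days, supplies, grace_days, horizon)
        p90, p270, p450 = classify_persistence(disc, (90, 270, 450))
        rows.append((pid, disc, p90, p270, p450))
    out = pd.DataFrame(
        rows,
        columns=["person_id", "discontinuation_day",
                 "persistent_90", "persistent_270", "persistent_450"],
    )
    out["discontinuation_day"] = out["discontinuation_day"].astype("Int64")
    return out
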