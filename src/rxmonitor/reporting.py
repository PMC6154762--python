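"""End-to-end pipeline orchestration, small-cell suppression, table rendering.

Estimates are always computed on true counts; disclosure control is applied
only when a table is rendered.  Any rendered count at or below the
suppression threshold (default 9) is masked as "<=9", and a proportion whose
numerator is masked is displayed as an upper bound computed with the
numerator replaced by the threshold (e.g. 9/12,964 -> "<=0.1").
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .claims_model import ClaimsDatabase, load_claims
from .cohort_builder import (AGE_GROUPS, DOSE_CATEGORIES, ExclusionLog,
                             build_cohort)
from .competing_risk import aalen_johansen, build_histories, CifCurve
from .config import NAMED_DRUGS, RunConfig
from .gee_modified_poisson import (DesignSpec, adjusted_proportions,
                                   fit_gee_poisson)
from .monitoring_metrics import (IncidenceEstimate, incidence_by_window,
                                 regular_monitoring, tests_relative)
from .persistence_engine import compute_persistence

__all__ = ["ReportBundle", "suppress_cells", "format_count",
           "format_proportion", "run_pipeline"]

logger = logging.getLogger(__name__)

KINDS = ("glucose", "prolactin")

#: minimum outcome events for a correlates model to be attempted
MIN_EVENTS_FOR_FIT = 10


# ---------------------------------------------------------------------------
# Cell suppression
# ---------------------------------------------------------------------------

def format_count(n: int, threshold: int = 9) -> str:
    """Render a count, masking it as ``<=T`` when n <= threshold."""
    return f"<={threshold}" if n <= threshold else f"{n}"


def format_proportion(numerator: int, denominator: int, threshold: int = 9,
                      percent: bool = True, digits: int = 1) -> str:
    """Render a proportion; a masked numerator becomes an upper bound with
    the numerator replaced by the threshold."""
    if denominator <= 0:
        return "-"
    scale = 100.0 if percent else 1.0
    if numerator <= threshold:
        bound = threshold / denominator * scale
        return f"<={bound:.{digits}f}"
    return f"{numerator / denominator * scale:.{digits}f}"


def suppress_cells(table: pd.DataFrame, threshold: int = 9,
                   count_cols: tuple[str, ...] | None = None,
                   pairs: dict[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Apply disclosure control to a table of counts and derived proportions.

    Parameters
    ----------
    table
        A frame of numeric cells.
    count_cols
        Columns holding counts; defaults to every column named ``n`` or
        starting with ``n_``.
    pairs
        Maps a proportion column to its ``(numerator_col, denominator_col)``;
        a masked numerator turns the proportion into a threshold-numerator
        upper bound.

    Returns a frame of strings; computation upstream is untouched.
    """
    out = table.copy().astype(object)
    if count_cols is None:
        count_cols = tuple(c for c in table.columns
                           if c == "n" or c.startswith("n_"))
    for col, (num_col, den_col) in (pairs or {}).items():
        rendered = []
        for _, row in table.iterrows():
            rendered.append(format_proportion(int(row[num_col]), int(row[den_col]),
                                              threshold))
        out[col] = rendered
    for col in count_cols:
        out[col] = [format_count(int(v), threshold) for v in table[col]]
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_TABLE1_FACTORS = {
    "provider_type": ("clinic", "hospital"),
    "setting": ("inpatient", "ambulatory"),
    "prescriber": ("nonpsychiatrist", "psychiatrist"),
    "sex": ("boy", "girl"),
    "age_group": AGE_GROUPS,
    "index_drug_category": NAMED_DRUGS + ("others",),
    "ap_type": ("FGA", "SGA", "both"),
    "cpz_dose_category": DOSE_CATEGORIES,
}


def cohort_summary(cohort: pd.DataFrame, persistence: pd.DataFrame) -> pd.DataFrame:
    """Characteristic counts and percentages for the total cohort and each
    persistent-user group (the sample-characteristics table layout)."""
    merged = cohort.merge(persistence, on="person_id")
    groups = {
        "total": merged,
        "p90": merged[merged["persistent_90"]],
        "p270": merged[merged["persistent_270"]],
        "p450": merged[merged["persistent_450"]],
    }
    rows = []
    for factor, levels in _TABLE1_FACTORS.items():
        for lvl in levels:
            row = {"characteristic": factor, "level": lvl}
            for gname, g in groups.items():
                n = int((g[factor] == lvl).sum())
                row[f"n_{gname}"] = n
                row[f"den_{gname}"] = len(g)
                row[f"pct_{gname}"] = 100.0 * n / len(g) if len(g) else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def monitoring_table(cohort: pd.DataFrame, persistence: pd.DataFrame,
                     tests_by_kind: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Monitoring and regular-monitoring estimates per window and kind
    (the per-window monitoring table layout)."""
    rows = []
    for kind in KINDS:
        tests = tests_by_kind[kind]
        plain = {e.window: e for e in incidence_by_window(cohort, persistence,
                                                          tests, kind)}
        regular = {e.window: e for e in regular_monitoring(cohort, persistence,
                                                           tests, kind,
                                                           "four_window")}
        combined = regular_monitoring(cohort, persistence, tests, kind,
                                      "three_window")[0]
        for window, est in plain.items():
            reg = regular.get(window)
            rows.append(_monitoring_row(kind, window, est, reg))
        rows.append(_monitoring_row(kind, "all_three", combined, None,
                                    scheme="three_window"))
    return pd.DataFrame(rows)


def _monitoring_row(kind: str, window: str, est: IncidenceEstimate,
                    reg: IncidenceEstimate | None, scheme: str = "four_window"):
    row = {
        "kind": kind, "window": window, "scheme": scheme,
        "n_persistent": est.denominator,
        "n_monitored": est.numerator,
        "proportion": est.proportion,
        "ci_low": est.ci_low, "ci_high": est.ci_high,
    }
    if reg is not None:
        row.update(n_regular=reg.numerator, regular_proportion=reg.proportion,
                   regular_ci_low=reg.ci_low, regular_ci_high=reg.ci_high)
    elif scheme == "three_window":
        row.update(n_regular=est.numerator, regular_proportion=est.proportion,
                   regular_ci_low=est.ci_low, regular_ci_high=est.ci_high)
    return row


def correlates_table(cohort: pd.DataFrame, tests_by_kind: dict[str, pd.DataFrame],
                     sensitivity_ap_type: bool = False) -> dict[str, pd.DataFrame | None]:
    """Crude and adjusted IPRs with adjusted incidence proportions, per kind.

    The outcome is baseline monitoring (a qualifying test in [-30, 0]).  The
    drug covariate is the individual index drug in the main analysis, the
    antipsychotic type in the sensitivity analysis.  Factor levels with zero
    events have no finite log-link estimate: such levels are dropped from the
    fit's data and reported with dashes.  If a kind has fewer than
    ``MIN_EVENTS_FOR_FIT`` events overall, no model is fitted (None).
    """
    drug_factor = "ap_type" if sensitivity_ap_type else "index_drug_category"
    factors = ("provider_type", "setting", "prescriber", "sex", "age_group",
               drug_factor, "cpz_dose_category")
    out: dict[str, pd.DataFrame | None] = {}
    for kind in KINDS:
        data = cohort.copy()
        tests = tests_by_kind[kind]
        baseline_ids = set(tests[(tests["rel_day"] >= -30)
                                 & (tests["rel_day"] <= 0)]["person_id"])
        data["outcome"] = data["person_id"].isin(baseline_ids).astype(int)
        if data["outcome"].sum() < MIN_EVENTS_FOR_FIT:
            logger.warning("correlates(%s): only %d events; model skipped",
                           kind, int(data["outcome"].sum()))
            out[kind] = None
            continue
        out[kind] = _correlates_one(data, factors, kind)
    return out


def _correlates_one(data: pd.DataFrame, factors: tuple[str, ...], kind: str
                    ) -> pd.DataFrame:
    # Drop levels that cannot support a finite log-link estimate.
    usable = data
    dropped: list[tuple[str, str]] = []
    for f in factors:
        ev = usable.groupby(f)["outcome"].sum()
        dead = [lvl for lvl, n in ev.items() if n == 0]
        for lvl in dead:
            dropped.append((f, lvl))
            usable = usable[usable[f] != lvl]
    # Factors reduced to one level carry no information.
    live_factors = tuple(f for f in factors if usable[f].nunique() > 1)
    spec = DesignSpec(outcome="outcome", factors=live_factors)
    try:
        fit = fit_gee_poisson(usable, spec)
    except (RuntimeError, ValueError) as err:
        logger.warning("correlates(%s): adjusted model failed (%s)", kind, err)
        return pd.DataFrame([{"kind": kind, "factor": f, "level": lvl,
                              "n": int((data[f] == lvl).sum()),
                              "dropped": True}
                             for f in factors for lvl in data[f].unique()])
    ipr = fit.ipr_table()
    rows = []
    for f in factors:
        if f not in live_factors:
            continue
        adj = adjusted_proportions(fit, usable, f)
        try:
            crude_fit = fit_gee_poisson(usable, DesignSpec(outcome="outcome",
                                                           factors=(f,)))
            crude_ipr_rows = {r["level"]: r
                              for _, r in crude_fit.ipr_table().iterrows()}
        except (RuntimeError, ValueError) as err:
            logger.warning("correlates(%s): crude model for %s failed (%s)",
                           kind, f, err)
            crude_ipr_rows = {}
        adj_ipr_rows = {r["level"]: r
                        for _, r in ipr[ipr["factor"] == f].iterrows()}
        ref = spec.references.get(f)
        for lvl, grp in data.groupby(f):
            if (f, lvl) in dropped:
                rows.append({"kind": kind, "factor": f, "level": lvl,
                             "n": len(grp), "n_events": int(grp["outcome"].sum()),
                             "crude_ip": float("nan"), "dropped": True})
                continue
            sub = usable[usable[f] == lvl]
            row = {
                "kind": kind, "factor": f, "level": lvl,
                "n": len(sub), "n_events": int(sub["outcome"].sum()),
                "crude_ip": float(sub["outcome"].mean()),
                "adjusted_ip": adj.get(lvl, float("nan")),
                "dropped": False,
                "is_reference": lvl == ref,
            }
            if lvl != ref:
                c = crude_ipr_rows.get(str(lvl))
                a = adj_ipr_rows.get(str(lvl))
                if c is not None:
                    row.update(crude_ipr=c["ipr"], crude_ci_low=c["ci_low"],
                               crude_ci_high=c["ci_high"])
                if a is not None:
                    row.update(adjusted_ipr=a["ipr"], adjusted_ci_low=a["ci_low"],
                               adjusted_ci_high=a["ci_high"])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """Everything one run produces, pre-suppression; render methods apply
    disclosure control at the end."""

    cohort: pd.DataFrame
    persistence: pd.DataFrame
    exclusions: ExclusionLog
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: dict[str, pd.DataFrame | None]
    cif: dict[str, CifCurve]
    metadata: dict = field(default_factory=dict)

    def rendered_table1(self, threshold: int = 9) -> pd.DataFrame:
        pairs = {f"pct_{g}": (f"n_{g}", f"den_{g}")
                 for g in ("total", "p90", "p270", "p450")}
        return suppress_cells(self.table1, threshold, pairs=pairs)

    def rendered_table2(self, threshold: int = 9) -> pd.DataFrame:
        t = self.table2.copy()
        pairs = {"proportion": ("n_monitored", "n_persistent")}
        count_cols = ["n_monitored"]
        has_regular = "n_regular" in t.columns
        if has_regular:
            no_reg = t["n_regular"].isna()
            t["n_regular"] = t["n_regular"].fillna(0).astype(int)
            pairs["regular_proportion"] = ("n_regular", "n_persistent")
            count_cols.append("n_regular")
        rendered = suppress_cells(t, threshold, count_cols=tuple(count_cols),
                                  pairs=pairs)
        # CIs on the same percent scale; no CI when the numerator is masked.
        for ci_col, num_col in (("ci_low", "n_monitored"),
                                ("ci_high", "n_monitored"),
                                ("regular_ci_low", "n_regular"),
                                ("regular_ci_high", "n_regular")):
            if ci_col not in t.columns:
                continue
            rendered[ci_col] = [
                "-" if t[num_col].iloc[i] <= threshold or pd.isna(v)
                else f"{100 * v:.1f}"
                for i, v in enumerate(t[ci_col])]
        if has_regular:  # baseline has no regular-monitoring column
            for col in ("n_regular", "regular_proportion",
                        "regular_ci_low", "regular_ci_high"):
                rendered.loc[no_reg, col] = "-"
        return rendered


def run_pipeline(config: RunConfig, db: ClaimsDatabase | None = None
                 ) -> ReportBundle:
    """Execute load -> link -> cohort -> persistence -> monitoring -> CIF ->
    correlates; deterministic given config and inputs."""
    config.validate()
    if db is None:
        db = load_claims(config.data_dir)
    stage_counts = {"persons": db.n_persons,
                    "prescriptions": len(db.prescriptions),
                    "procedures": len(db.procedures)}
    sel = config.selection
    cohort, exclusions = build_cohort(db, sel, config.drug_dictionary)
    stage_counts["candidates"] = len(cohort) + exclusions.n_excluded
    stage_counts["cohort"] = len(cohort)
    stage_counts["exclusions"] = exclusions.counts
    logger.info("cohort: %s", stage_counts)

    if not len(cohort):
        empty = pd.DataFrame()
        return ReportBundle(cohort, pd.DataFrame(
            columns=["person_id", "discontinuation_day", "persistent_90",
                     "persistent_270", "persistent_450"]),
            exclusions, empty, empty, {k: None for k in KINDS}, {},
            metadata={"stage_counts": stage_counts, "config_hash": _config_hash(config),
                      "seed": config.seed, "version": __version__})

    persistence = compute_persistence(cohort, db.prescriptions,
                                      config.drug_dictionary.codes,
                                      sel.grace_days, sel.horizons[-1])
    for h in sel.horizons:
        stage_counts[f"persistent_{h}"] = int(persistence[f"persistent_{h}"].sum())

    tests_by_kind = {k: tests_relative(db.procedures, cohort, k) for k in KINDS}

    table1 = cohort_summary(cohort, persistence)
    table2 = (monitoring_table(cohort, persistence, tests_by_kind)
              if config.run_monitoring else pd.DataFrame())
    cif = {}
    if config.run_cif:
        for kind in KINDS:
            hist = build_histories(cohort, persistence, tests_by_kind[kind],
                                   config.tie_monitored_wins)
            cif[kind] = aalen_johansen(hist)
    table3 = (correlates_table(cohort, tests_by_kind, config.sensitivity_ap_type)
              if config.run_correlates else {k: None for k in KINDS})

    return ReportBundle(
        cohort=cohort, persistence=persistence, exclusions=exclusions,
        table1=table1, table2=table2, table3=table3, cif=cif,
        metadata={"stage_counts": stage_counts,
                  "config_hash": _config_hash(config),
                  "seed": config.seed, "version": __version__},
    )


def _config_hash(config: RunConfig) -> str:
    payload = {
        "selection": vars(config.selection).copy(),
        "suppression_threshold": config.suppression_threshold,
        "sensitivity_ap_type": config.sensitivity_ap_type,
        "drug_dictionary": config.drug_dictionary.to_mapping(),
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_bundle(bundle: ReportBundle, out_dir: Path | str,
                 threshold: int = 9) -> None:
    """Write the rendered tables, CIF curves, exclusion log and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cohort.to_csv(out / "cohort.csv", index=False)
    bundle.persistence.to_csv(out / "persistence.csv", index=False)
    if len(bundle.table1):
        bundle.rendered_table1(threshold).to_csv(out / "table1.csv", index=False)
    if len(bundle.table2):
        bundle.rendered_table2(threshold).to_csv(out / "table2.csv", index=False)
    for kind, t3 in bundle.table3.items():
        if t3 is not None:
            t3.to_csv(out / f"table3_{kind}.csv", index=False)
    for kind, curve in bundle.cif.items():
        if curve is not None:
            curve.to_frame().to_csv(out / f"cif_{kind}.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps(
        {"counts": bundle.exclusions.counts,
         "reasons": {str(k): v for k, v in bundle.exclusions.reasons.items()}},
        indent=1))
    (out / "metadata.json").write_text(json.dumps(bundle.metadata, indent=1,
                                                  default=str))
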