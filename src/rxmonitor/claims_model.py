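"""Claims data model: record schemas, the CSV dialect, and person linkage.

Administrative claims arrive as four flat tables -- enrollment spans,
prescription fills, laboratory/procedure events, and diagnoses.  Records are
keyed by a *pair* of opaque patient identifiers: ``id1`` is derived from the
insurance certificate and ``id2`` from demographic fields, and either may be
missing or may change over time (job changes break ``id1``, family-name
changes break ``id2``).  Person identity is therefore resolved by transitive
closure over shared identifier components, producing a canonical integer
person key used by every downstream stage.

All dates are integer day offsets from a run-level epoch: the analysis logic
is entirely in relative days, so calendar parsing -- if any -- belongs at the
file boundary, outside this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GLUCOSE_CODES",
    "PROLACTIN_CODES",
    "SchemaError",
    "RecordError",
    "PersonMap",
    "ClaimsDatabase",
    "classify_procedure",
    "resolve_person_ids",
    "load_claims",
    "write_claims",
]

#: Procedure codes counted as glucose monitoring (blood glucose, HbA1c).
GLUCOSE_CODES = frozenset({"160019410", "160010010"})
#: Procedure code counted as prolactin monitoring.
PROLACTIN_CODES = frozenset({"160032310"})

_ICD10_RE = re.compile(r"^[A-Z]\d+(\.\d+)?$")

ENROLLMENT_COLUMNS = ("id1", "id2", "sex", "age_years", "enroll_start", "enroll_end")
#: Optional enrollment columns giving the claims-completeness interval.
ENROLLMENT_OPTIONAL = ("complete_start", "complete_end")
PRESCRIPTION_COLUMNS = (
    "id1", "id2", "institution_id", "fill_date", "drug_code", "days_supply",
    "cpz_equiv_daily_mg", "drug_class", "prescriber", "setting", "provider_type",
)
PROCEDURE_COLUMNS = ("id1", "id2", "date", "procedure_code")
DIAGNOSIS_COLUMNS = ("id1", "id2", "date", "icd10", "definitive")

_SEX_LEVELS = ("boy", "girl")
_CLASS_LEVELS = ("FGA", "SGA")
_PRESCRIBER_LEVELS = ("psychiatrist", "nonpsychiatrist")
_SETTING_LEVELS = ("inpatient", "ambulatory")
_PROVIDER_LEVELS = ("clinic", "hospital")


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class RecordError(ValueError):
    """A row-level value failed validation; carries the offending row index."""

    def __init__(self, table: str, row: int, message: str):
        self.table = table
        self.row = row
        super().__init__(f"{table} row {row}: {message}")


def classify_procedure(code: str) -> str:
    """Classify a procedure code as ``glucose``, ``prolactin`` or ``other``.

    Blood glucose (160019410) and HbA1c (160010010) both count as glucose
    monitoring; 160032310 is the prolactin assay.  Unknown codes are simply
    ``other`` -- a claims extract contains thousands of unrelated procedures.
    """
    if code in GLUCOSE_CODES:
        return "glucose"
    if code in PROLACTIN_CODES:
        return "prolactin"
    return "other"


# ---------------------------------------------------------------------------
# Person linkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersonMap:
    """Mapping from each ``(id1, id2)`` identifier pair to a canonical person key.

    Two pairs sharing a non-empty ``id1`` or a non-empty ``id2`` belong to the
    same person (transitive closure).  Keys are small integers, numbered in
    order of first appearance of each person's earliest pair.
    """

    pair_to_person: Mapping[tuple[str, str], int]

    @property
    def n_persons(self) -> int:
        return len(set(self.pair_to_person.values()))

    def person_of(self, id1: str, id2: str) -> int:
        return self.pair_to_person[(id1, id2)]


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def resolve_person_ids(pairs: Iterable[tuple[str, str]]) -> PersonMap:
    """Resolve identifier pairs into canonical person keys.

    Union-find over the pairs, joining on shared non-empty components.  An
    empty component never links (a missing identifier carries no identity
    information).

    Raises
    ------
    ValueError
        If a pair has both components empty.
    """
    pairs = list(dict.fromkeys(tuple(p) for p in pairs))  # dedupe, keep order
    uf = _UnionFind()
    by_id1: dict[str, int] = {}
    by_id2: dict[str, int] = {}
    for i, (id1, id2) in enumerate(pairs):
        if not id1 and not id2:
            raise ValueError(f"identifier pair #{i} has both components empty")
        uf.add(i)
        if id1:
            if id1 in by_id1:
                uf.union(i, by_id1[id1])
            else:
                by_id1[id1] = i
        if id2:
            if id2 in by_id2:
                uf.union(i, by_id2[id2])
            else:
                by_id2[id2] = i
    # Number persons by first appearance of their component root.
    key_of_root: dict[int, int] = {}
    mapping: dict[tuple[str, str], int] = {}
    for i, pair in enumerate(pairs):
        root = uf.find(i)
        if root not in key_of_root:
            key_of_root[root] = len(key_of_root)
        mapping[pair] = key_of_root[root]
    return PersonMap(mapping)


# ---------------------------------------------------------------------------
# Database container
# ---------------------------------------------------------------------------

@dataclass
class ClaimsDatabase:
    """The four linked record tables plus the resolved person map.

    Each table carries a ``person_id`` column added at load/link time; the raw
    ``id1``/``id2`` columns are preserved so a write/load round trip is exact.
    """

    enrollment: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame
    diagnoses: pd.DataFrame
    persons: PersonMap = field(repr=False)

    @property
    def n_persons(self) -> int:
        return self.persons.n_persons

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "enrollment": self.enrollment,
            "prescriptions": self.prescriptions,
            "procedures": self.procedures,
            "diagnoses": self.diagnoses,
        }


def link_tables(
    enrollment: pd.DataFrame,
    prescriptions: pd.DataFrame,
    procedures: pd.DataFrame,
    diagnoses: pd.DataFrame,
) -> ClaimsDatabase:
    """Resolve person identity across the four tables and attach person keys."""
    all_pairs: list[tuple[str, str]] = []
    for df in (enrollment, prescriptions, procedures, diagnoses):
        if len(df):
            all_pairs.extend(zip(df["id1"], df["id2"]))
    persons = resolve_person_ids(all_pairs) if all_pairs else PersonMap({})
    out = []
    for df in (enrollment, prescriptions, procedures, diagnoses):
        df = df.copy()
        if len(df):
            df["person_id"] = [
                persons.person_of(a, b) for a, b in zip(df["id1"], df["id2"])
            ]
        else:
            df["person_id"] = pd.Series([], dtype=int)
        out.append(df)
    return ClaimsDatabase(*out, persons=persons)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_table(path: Path, table: str, columns: Sequence[str],
                optional: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} ({path}): missing column(s) {missing}")
    keep = list(columns) + [c for c in optional if c in df.columns]
    return df[keep]


def _to_int(df: pd.DataFrame, table: str, col: str) -> pd.Series:
    def conv(i_v):
        i, v = i_v
        try:
            return int(v)
        except (TypeError, ValueError):
            raise RecordError(table, i, f"column {col!r}: cannot parse {v!r} as a day/integer")
    return pd.Series([conv(iv) for iv in enumerate(df[col])], index=df.index, dtype="int64")


def _check_levels(df: pd.DataFrame, table: str, col: str, levels: Sequence[str]) -> None:
    bad = ~df[col].isin(levels)
    if bad.any():
        i = int(df.index[bad][0])
        raise RecordError(table, i, f"column {col!r}: {df[col].iloc[i]!r} not in {list(levels)}")


def parse_enrollment(df: pd.DataFrame) -> pd.DataFrame:
    t = "enrollment"
    df = df.copy()
    for col in ("age_years", "enroll_start", "enroll_end"):
        df[col] = _to_int(df, t, col)
    for col in ("complete_start", "complete_end"):
        if col in df.columns:
            df[col] = _to_int(df, t, col)
    _check_levels(df, t, "sex", _SEX_LEVELS)
    bad = df["enroll_start"] > df["enroll_end"]
    if bad.any():
        raise RecordError(t, int(df.index[bad][0]), "enroll_start > enroll_end")
    if (df["age_years"] < 0).any():
        raise RecordError(t, int(df.index[df["age_years"] < 0][0]), "age_years < 0")
    _require_some_id(df, t)
    return df


def parse_prescriptions(df: pd.DataFrame) -> pd.DataFrame:
    t = "prescriptions"
    df = df.copy()
    for col in ("fill_date", "days_supply"):
        df[col] = _to_int(df, t, col)
    df["cpz_equiv_daily_mg"] = pd.to_numeric(df["cpz_equiv_daily_mg"], errors="coerce")
    if df["cpz_equiv_daily_mg"].isna().any():
        raise RecordError(t, int(df.index[df["cpz_equiv_daily_mg"].isna()][0]),
                          "cpz_equiv_daily_mg not numeric")
    if (df["cpz_equiv_daily_mg"] < 0).any():
        raise RecordError(t, int(df.index[df["cpz_equiv_daily_mg"] < 0][0]),
                          "cpz_equiv_daily_mg < 0")
    if (df["days_supply"] < 1).any():
        raise RecordError(t, int(df.index[df["days_supply"] < 1][0]), "days_supply < 1")
    _check_levels(df, t, "drug_class", _CLASS_LEVELS)
    _check_levels(df, t, "prescriber", _PRESCRIBER_LEVELS)
    _check_levels(df, t, "setting", _SETTING_LEVELS)
    _check_levels(df, t, "provider_type", _PROVIDER_LEVELS)
    _require_some_id(df, t)
    return df


def parse_procedures(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["date"] = _to_int(df, "procedures", "date")
    _require_some_id(df, "procedures")
    return df


def parse_diagnoses(df: pd.DataFrame) -> pd.DataFrame:
    t = "diagnoses"
    df = df.copy()
    df["date"] = _to_int(df, t, "date")
    bad = ~df["icd10"].map(lambda c: bool(_ICD10_RE.match(c)))
    if bad.any():
        i = int(df.index[bad][0])
        raise RecordError(t, i, f"icd10 code {df['icd10'].iloc[i]!r} malformed")
    df["definitive"] = df["definitive"].map(
        {"true": True, "false": False, "True": True, "False": False, "1": True, "0": False}
    )
    if df["definitive"].isna().any():
        raise RecordError(t, int(df.index[df["definitive"].isna()][0]),
                          "definitive flag must be true/false")
    df["definitive"] = df["definitive"].astype(bool)
    _require_some_id(df, t)
    return df


def _require_some_id(df: pd.DataFrame, table: str) -> None:
    bad = (df["id1"] == "") & (df["id2"] == "")
    if bad.any():
        raise RecordError(table, int(df.index[bad][0]), "both id1 and id2 empty")


_PARSERS = {
    "enrollment": (ENROLLMENT_COLUMNS, ENROLLMENT_OPTIONAL, parse_enrollment),
    "prescriptions": (PRESCRIPTION_COLUMNS, (), parse_prescriptions),
    "procedures": (PROCEDURE_COLUMNS, (), parse_procedures),
    "diagnoses": (DIAGNOSIS_COLUMNS, (), parse_diagnoses),
}


def load_claims(paths: Mapping[str, Path] | str | Path, config=None) -> ClaimsDatabase:
    """Load, validate and link the four claims tables.

    Parameters
    ----------
    paths
        Either a directory containing ``enrollment.csv``, ``prescriptions.csv``,
        ``procedures.csv`` and ``diagnoses.csv``, or a mapping from table name
        to file path.
    config
        Accepted for interface symmetry; the schema itself is fixed.

    Raises
    ------
    SchemaError
        If a required column is missing.
    RecordError
        If a row value fails validation (carries the row index).
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in _PARSERS}
    parsed = {}
    for name, (cols, opt, parser) in _PARSERS.items():
        parsed[name] = parser(_read_table(Path(paths[name]), name, cols, opt))
    return link_tables(parsed["enrollment"], parsed["prescriptions"],
                       parsed["procedures"], parsed["diagnoses"])


def write_claims(db: ClaimsDatabase, out_dir: Path | str) -> dict[str, Path]:
    """Write the four tables in the CSV dialect; returns the paths written.

    The ``person_id`` column is an artifact of linkage and is not part of the
    dialect, so it is dropped on write; a subsequent :func:`load_claims`
    re-derives it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in db.tables().items():
        df = df.drop(columns=["person_id"], errors="ignore").copy()
        if name == "diagnoses" and len(df):
            df["definitive"] = df["definitive"].map({True: "true", False: "false"})
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written
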