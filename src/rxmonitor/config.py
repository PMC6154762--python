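"""Run configuration: antipsychotic dictionary, selection rules, pipeline settings.

The antipsychotic dictionary is deliberately a user-editable table: real claims
systems use national drug codes and locally maintained chlorpromazine-equivalence
factors, so the package ships a synthetic default dictionary covering the eight
individually reported antipsychotics plus a catch-all ninth, and accepts a
replacement from the run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DrugInfo",
    "DrugDictionary",
    "DEFAULT_DRUG_DICTIONARY",
    "SelectionConfig",
    "DEFAULT_DIABETES_CODES",
    "RunConfig",
    "NAMED_DRUGS",
]

#: The eight individually reported antipsychotics; anything else is "others".
NAMED_DRUGS = (
    "aripiprazole", "chlorpromazine", "haloperidol", "olanzapine",
    "prochlorperazine", "quetiapine", "risperidone", "sulpiride",
)


@dataclass(frozen=True)
class DrugInfo:
    name: str
    drug_class: str          # FGA or SGA
    typical_cpz_mg: float    # typical chlorpromazine-equivalent daily dose, mg


class DrugDictionary:
    """Code -> antipsychotic lookup; codes absent here are not antipsychotics."""

    def __init__(self, entries: Mapping[str, DrugInfo]):
        self._entries = dict(entries)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> DrugInfo:
        try:
            return self._entries[code]
        except KeyError:
            raise KeyError(
                f"drug code {code!r} is not in the antipsychotic dictionary; "
                "add it to the configuration if it is an antipsychotic"
            ) from None

    def items(self):
        return self._entries.items()

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping]) -> "DrugDictionary":
        return cls({
            code: DrugInfo(m["name"], m["drug_class"], float(m.get("typical_cpz_mg", 100.0)))
            for code, m in mapping.items()
        })

    def to_mapping(self) -> dict[str, dict]:
        return {c: asdict(i) for c, i in self._entries.items()}


# Synthetic codes (the real national codes are jurisdiction-specific).  Typical
# CPZ-equivalent daily doses are order-of-magnitude pediatric values.
DEFAULT_DRUG_DICTIONARY = DrugDictionary({
    "AP001": DrugInfo("aripiprazole", "SGA", 75.0),
    "AP002": DrugInfo("chlorpromazine", "FGA", 50.0),
    "AP003": DrugInfo("haloperidol", "FGA", 100.0),
    "AP004": DrugInfo("olanzapine", "SGA", 200.0),
    "AP005": DrugInfo("prochlorperazine", "FGA", 40.0),
    "AP006": DrugInfo("quetiapine", "SGA", 110.0),
    "AP007": DrugInfo("risperidone", "SGA", 80.0),
    "AP008": DrugInfo("sulpiride", "FGA", 30.0),
    "AP009": DrugInfo("blonanserin", "SGA", 120.0),
})


def _diabetes_codes() -> tuple[str, ...]:
    # Diabetes-with-complication and unspecified subcodes used for exclusion:
    # E10/E11/E13/E14 with fourth digit .1-.5 or .9.
    return tuple(
        f"E{stem}.{d}" for stem in (10, 11, 13, 14) for d in (1, 2, 3, 4, 5, 9)
    )


DEFAULT_DIABETES_CODES = _diabetes_codes()


@dataclass
class SelectionConfig:
    """New-user selection rules.

    ``accrual_window`` is the inclusive day interval in which a first fill
    qualifies as an index date.  A patient must be enrolled from at least
    ``pre_enroll_days`` before the index through ``post_enroll_days`` after it
    (450 days of follow-up plus the 30-day grace period), be free of
    antipsychotic fills during the ``washout_days`` before the index, and have
    no definitive diabetes diagnosis on or before the index.
    """

    accrual_window: tuple[int, int] = (365, 729)
    washout_days: int = 180
    pre_enroll_days: int = 180
    post_enroll_days: int = 480
    diabetes_codes: tuple[str, ...] = DEFAULT_DIABETES_CODES
    grace_days: int = 30
    horizons: tuple[int, int, int] = (90, 270, 450)
    max_age_years: int = 18

    def validate(self) -> None:
        if self.accrual_window[0] > self.accrual_window[1]:
            raise ValueError("accrual window is empty-ordered")
        for name in ("washout_days", "pre_enroll_days", "post_enroll_days", "grace_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if tuple(sorted(self.horizons)) != tuple(self.horizons):
            raise ValueError("horizons must be increasing")


@dataclass
class RunConfig:
    """Top-level pipeline configuration (YAML- or dict-loadable)."""

    data_dir: str = "."
    out_dir: str = "out"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    drug_dictionary: DrugDictionary = field(default_factory=lambda: DEFAULT_DRUG_DICTIONARY)
    suppression_threshold: int = 9
    seed: int = 0
    #: analysis toggles
    run_monitoring: bool = True
    run_cif: bool = True
    run_correlates: bool = True
    #: use antipsychotic type (FGA/SGA/both) instead of individual drug
    sensitivity_ap_type: bool = False
    #: same-day monitoring-vs-discontinuation tie resolution
    tie_monitored_wins: bool = True

    def validate(self) -> None:
        if self.suppression_threshold < 0:
            raise ValueError("suppression threshold must be >= 0")
        self.selection.validate()

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sel = d.pop("selection", {})
        if isinstance(sel, Mapping):
            sel = dict(sel)
            if "accrual_window" in sel:
                sel["accrual_window"] = tuple(sel["accrual_window"])
            if "diabetes_codes" in sel:
                sel["diabetes_codes"] = tuple(sel["diabetes_codes"])
            if "horizons" in sel:
                sel["horizons"] = tuple(sel["horizons"])
            sel = SelectionConfig(**sel)
        dd = d.pop("drug_dictionary", None)
        drug_dict = DrugDictionary.from_mapping(dd) if dd else DEFAULT_DRUG_DICTIONARY
        cfg = cls(selection=sel, drug_dictionary=drug_dict, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
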