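"""Case-ascertainment and exposure rules over registry visit tables.

Pure table-in/table-out implementations of the diagnostic algorithm for
idiopathic inflammatory myopathies (IIMs) in hospital-register data:

* the index case definition — in the inpatient-only era (1997-2000) one
  hospitalisation with IIM as main diagnosis; once outpatient data exist
  (2001-2016) at least two visits with IIM codes of which at least one is a
  main diagnosis — restricted to visits from five specialist departments;
* the relative exposure definition — primary: any main-diagnosis IIM visit
  1987-2017 (ICD-9 710D/710E before the era switch, ICD-10 M33.x/G72.4
  after); strict: the index case definition applied to the relative;
* a screen for inherited IIM mimics (muscular dystrophies and metabolic
  myopathies) among members of affected family units.

The shipped mimic code list is a reconstruction from the ICD chapters for
muscular dystrophies (G71.0-G71.3), other specified myopathies (G72.3) and
glycogen-storage/lipid-storage disease (E74.0, E75.2), with ICD-9 analogues
359.0/359.1/271.0; it is configurable because register studies typically
curate their own list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ICD9_IIM_CODES",
    "ICD10_IIM_CODES",
    "ACCEPTED_DEPARTMENTS",
    "DEFAULT_MIMIC_ICD9",
    "DEFAULT_MIMIC_ICD10",
    "CaseDefinitionRule",
    "RelativeExposureRule",
    "is_iim_code",
    "ascertain_cases",
    "classify_subtype",
    "determine_relative_exposure",
    "exposure_flags",
    "screen_mimics",
]

ICD9_IIM_CODES = frozenset({"710D", "710E"})
# "M33" is a code family: any fourth-character subcode qualifies.
ICD10_IIM_CODES = ("M33", "G72.4")
ACCEPTED_DEPARTMENTS = (
    "internal_medicine",
    "rheumatology",
    "dermatology",
    "neurology",
    "paediatrics",
)
DEFAULT_MIMIC_ICD10 = ("G71.0", "G71.1", "G71.2", "G71.3", "G72.3",
                       "E74.0", "E75.2")
DEFAULT_MIMIC_ICD9 = ("359.0", "359.1", "271.0")


def is_iim_code(code: str, icd_version: str) -> bool:
    """True if the (code, version) pair denotes IIM."""
    if icd_version == "ICD9":
        return code in ICD9_IIM_CODES
    return code == "G72.4" or code.startswith("M33")


@dataclass
class CaseDefinitionRule:
    """Index case definition with its two register eras.

    era 1 (inpatient register only): >= 1 hospitalisation with IIM as the
    main diagnosis.  era 2 (inpatient + outpatient): >= 2 visits with IIM
    codes, at least one of them a main diagnosis.  Only visits from the
    accepted specialist departments count in either era.
    """

    era1_window: tuple[str, str] = ("1997-01-01", "2000-12-31")
    era2_window: tuple[str, str] = ("2001-01-01", "2016-12-31")
    accepted_departments: tuple[str, ...] = ACCEPTED_DEPARTMENTS

    def __post_init__(self) -> None:
        e1 = tuple(pd.Timestamp(d) for d in self.era1_window)
        e2 = tuple(pd.Timestamp(d) for d in self.era2_window)
        if not (e1[0] <= e1[1] < e2[0] <= e2[1]):
            raise ValueError("era windows must be ordered and non-overlapping")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaseDefinitionRule":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            era1_window=tuple(d["era1_window"]),
            era2_window=tuple(d["era2_window"]),
            accepted_departments=tuple(d["accepted_departments"]),
        )


@dataclass
class RelativeExposureRule:
    """Exposure definition for first-degree relatives.

    ``primary``: >= 1 visit with IIM as main diagnosis anywhere in the
    exposure window (ICD-9 codes before the era switch, ICD-10 after).
    ``strict``: the full index case definition must hold for the relative.
    """

    mode: str = "primary"
    window: tuple[int, int] = (1987, 2017)
    case_rule: CaseDefinitionRule = field(default_factory=CaseDefinitionRule)

    def __post_init__(self) -> None:
        if self.mode not in ("primary", "strict"):
            raise ValueError(f"mode must be 'primary' or 'strict', got {self.mode!r}")


def _prep(visits: pd.DataFrame) -> pd.DataFrame:
    v = visits.copy()
    if not pd.api.types.is_datetime64_any_dtype(v["visit_date"]):
        v["visit_date"] = pd.to_datetime(v["visit_date"])
    return v


def _iim_mask(v: pd.DataFrame) -> pd.Series:
    icd9 = v["icd_version"].eq("ICD9") & v["icd_code"].isin(ICD9_IIM_CODES)
    icd10 = v["icd_version"].eq("ICD10") & (
        v["icd_code"].eq("G72.4") | v["icd_code"].str.startswith("M33")
    )
    return icd9 | icd10


def ascertain_cases(
    visits: pd.DataFrame,
    rule: CaseDefinitionRule | None = None,
    persons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the index case definition to a visit table.

    Returns one row per ascertained case with ``person_id`` and
    ``diagnosis_date`` (the earliest qualifying IIM visit).  When a persons
    table with ``birth_year`` is supplied, ``age_at_diagnosis`` and
    ``subtype`` (JIIM / DM / other_IIM) are added.

    Visits with unknown departments or code systems are logged and treated as
    non-qualifying rather than raising.
    """
    rule = rule or CaseDefinitionRule()
    v = _prep(visits)

    unknown_dept = ~v["department"].isin(list(rule.accepted_departments) + ["other"])
    if unknown_dept.any():
        logger.warning(
            "%d visits with unknown department treated as non-qualifying",
            int(unknown_dept.sum()),
        )
    v = v[v["department"].isin(rule.accepted_departments) & _iim_mask(v)]

    e1_lo, e1_hi = (pd.Timestamp(d) for d in rule.era1_window)
    e2_lo, e2_hi = (pd.Timestamp(d) for d in rule.era2_window)

    era1 = v[
        v["visit_date"].between(e1_lo, e1_hi)
        & v["setting"].eq("inpatient")
        & v["main_diagnosis"]
    ]
    era1_dx = era1.groupby("person_id")["visit_date"].min()

    era2 = v[v["visit_date"].between(e2_lo, e2_hi)]
    g = era2.groupby("person_id")
    era2_ok = (g.size() >= 2) & g["main_diagnosis"].any()
    era2_dx = g["visit_date"].min()[era2_ok[era2_ok].index]

    dx = pd.concat([era1_dx, era2_dx]).groupby(level=0).min()
    cases = dx.rename("diagnosis_date").rename_axis("person_id").reset_index()
    cases = cases.sort_values("person_id").reset_index(drop=True)

    if persons is not None:
        by = persons.set_index("person_id")["birth_year"]
        cases["age_at_diagnosis"] = (
            cases["diagnosis_date"].dt.year - cases["person_id"].map(by)
        )
        cases["subtype"] = [
            classify_subtype(pid, age, v)
            for pid, age in zip(cases["person_id"], cases["age_at_diagnosis"])
        ]
    return cases


def classify_subtype(
    person_id, age_at_diagnosis: float, iim_visits: pd.DataFrame
) -> str:
    """JIIM if diagnosed at <= 18 years; else DM for M33.1, otherwise other_IIM.

    When several codes appear, the code on the earliest main-diagnosis visit
    decides (deterministic tie-break).
    """
    if age_at_diagnosis <= 18:
        return "JIIM"
    mine = iim_visits[
        iim_visits["person_id"].eq(person_id) & iim_visits["main_diagnosis"]
    ].sort_values("visit_date")
    if len(mine) == 0:
        mine = iim_visits[iim_visits["person_id"].eq(person_id)].sort_values(
            "visit_date"
        )
    code = mine["icd_code"].iloc[0] if len(mine) else ""
    return "DM" if code == "M33.1" else "other_IIM"


def exposure_flags(
    visits: pd.DataFrame, rule: RelativeExposureRule | None = None
) -> pd.Series:
    """Exposure status for every person appearing in the visit table.

    Returns a boolean Series indexed by person_id; persons without visits are
    simply absent (unexposed).
    """
    rule = rule or RelativeExposureRule()
    if rule.mode == "strict":
        cases = ascertain_cases(visits, rule.case_rule)
        flags = pd.Series(True, index=cases["person_id"])
        flags.index.name = "person_id"
        return flags
    v = _prep(visits)
    lo = pd.Timestamp(year=rule.window[0], month=1, day=1)
    hi = pd.Timestamp(year=rule.window[1], month=12, day=31)
    qual = v[
        v["visit_date"].between(lo, hi) & v["main_diagnosis"] & _iim_mask(v)
    ]
    flags = qual.groupby("person_id").size() > 0
    flags.index.name = "person_id"
    return flags


def determine_relative_exposure(
    relative_id, visits: pd.DataFrame, rule: RelativeExposureRule | None = None
) -> bool:
    """Exposure status of a single relative under the given rule."""
    flags = exposure_flags(visits, rule)
    return bool(flags.get(relative_id, False))


def screen_mimics(
    person_ids,
    visits: pd.DataFrame,
    mimic_codes_icd10=DEFAULT_MIMIC_ICD10,
    mimic_codes_icd9=DEFAULT_MIMIC_ICD9,
    window: tuple[int, int] = (1987, 2017),
) -> pd.DataFrame:
    """Flag persons with >= 1 main-diagnosis mimic-coded visit in the window.

    Intended for members of family units affected by IIM, to quantify the
    risk that inherited myopathies were miscoded as IIM.
    """
    codes = set(mimic_codes_icd10) | set(mimic_codes_icd9)
    if not codes:
        raise ValueError("mimic code list must not be empty")
    v = _prep(visits)
    lo = pd.Timestamp(year=window[0], month=1, day=1)
    hi = pd.Timestamp(year=window[1], month=12, day=31)
    mask9 = v["icd_version"].eq("ICD9") & v["icd_code"].isin(set(mimic_codes_icd9))
    mask10 = v["icd_version"].eq("ICD10") & v["icd_code"].isin(set(mimic_codes_icd10))
    hit = v[
        v["person_id"].isin(person_ids)
        & v["visit_date"].between(lo, hi)
        & v["main_diagnosis"]
        & (mask9 | mask10)
    ]
    flagged = set(hit["person_id"])
    return pd.DataFrame(
        {
            "person_id": list(person_ids),
            "mimic_flag": [pid in flagged for pid in person_ids],
        }
    )
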