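"""Synthetic population, multi-generation and patient registers.

Emulates the linked national registers a family-based disease study draws on:
a total-population register (identity, sex, birth/death years, region), a
multi-generation register (parental links for nuclear families) and a patient
register (healthcare visits with era-appropriate ICD coding).  Disease status
comes from an additive liability-threshold model, so downstream estimators can
be checked against the generating heritability.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from the configuration, making every output table bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .phenotypes import (
    ICD9_IIM_CODES,
    ICD10_IIM_CODES,
    DEFAULT_MIMIC_ICD9,
    DEFAULT_MIMIC_ICD10,
    ACCEPTED_DEPARTMENTS,
)

__all__ = [
    "SimulatedRegistry",
    "simulate_pedigrees",
    "pedigree_links",
    "assign_liabilities",
    "generate_visit_records",
    "simulate_registry",
    "write_registry",
]

_BACKGROUND_CODES = ["I10", "J06", "K21", "E11", "M54"]
_BACKGROUND_CODES_ICD9 = ["401", "460", "530", "250", "724"]
_DEPT_WEIGHTS = [0.25, 0.40, 0.10, 0.18, 0.07]  # over the accepted departments


@dataclass
class SimulatedRegistry:
    """Bundle of the simulated register tables."""

    persons: pd.DataFrame
    pedigree: pd.DataFrame
    liabilities: pd.DataFrame
    visits: pd.DataFrame
    config: SimulationConfig

    @property
    def threshold(self) -> float:
        return float(stats.norm.isf(self.config.prevalence_K))


def simulate_pedigrees(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw nuclear families: two founders plus Poisson(mean_offspring) children.

    Returns a persons table with parental-link columns (``mother_id``,
    ``father_id`` are null for founders).  Regions are drawn per family so
    that household members share a residential area.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_fam = config.n_families
    lo, hi = config.birth_year_range

    mother_by = rng.integers(lo, hi + 1, size=n_fam)
    father_by = np.clip(mother_by + rng.integers(-5, 6, size=n_fam), lo, hi)
    n_children = rng.poisson(config.mean_offspring, size=n_fam)
    regions = rng.integers(0, config.region_count, size=n_fam)

    fam_ids, person_ids, sexes, births = [], [], [], []
    mothers, fathers, regs, founder = [], [], [], []
    next_id = 0
    for fam in range(n_fam):
        m_id, f_id = next_id, next_id + 1
        next_id += 2
        fam_ids += [fam, fam]
        person_ids += [m_id, f_id]
        sexes += ["female", "male"]
        births += [int(mother_by[fam]), int(father_by[fam])]
        mothers += [-1, -1]
        fathers += [-1, -1]
        regs += [int(regions[fam])] * 2
        founder += [True, True]
        k = int(n_children[fam])
        if k:
            child_ids = list(range(next_id, next_id + k))
            next_id += k
            gaps = rng.integers(20, 41, size=k)
            fam_ids += [fam] * k
            person_ids += child_ids
            sexes += list(
                np.where(rng.random(k) < 0.5, "female", "male")
            )
            births += [int(mother_by[fam] + g) for g in gaps]
            mothers += [m_id] * k
            fathers += [f_id] * k
            regs += [int(regions[fam])] * k
            founder += [False] * k

    persons = pd.DataFrame(
        {
            "person_id": np.array(person_ids, dtype=np.int64),
            "family_id": np.array(fam_ids, dtype=np.int64),
            "sex": pd.Categorical(sexes, categories=["female", "male"]),
            "birth_year": np.array(births, dtype=np.int64),
            "mother_id": np.array(mothers, dtype=np.int64),
            "father_id": np.array(fathers, dtype=np.int64),
            "region": np.array(regs, dtype=np.int64),
            "is_founder": np.array(founder, dtype=bool),
        }
    )

    # birth country: founders may be foreign-born, children are domestic
    n = len(persons)
    foreign = (rng.random(n) < config.foreign_born_rate) & persons[
        "is_founder"
    ].to_numpy()
    persons["birth_country"] = np.where(foreign, "foreign", "domestic")

    persons["death_year"] = _draw_death_years(persons["birth_year"].to_numpy(),
                                              config, rng)
    return persons


def _draw_death_years(
    birth_years: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Piecewise-geometric death ages from the banded annual hazard.

    Deaths after the registry horizon are recorded as NaN (alive as far as
    the simulated registers can tell).
    """
    n = len(birth_years)
    bands = sorted(config.death_hazard.items())
    death_age = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    for i, (start, hazard) in enumerate(bands):
        end = bands[i + 1][0] if i + 1 < len(bands) else 110
        span = end - start
        if hazard <= 0:
            continue
        # geometric draw within the band for those still alive at its start
        u = rng.random(n)
        within = np.floor(np.log(u) / np.log1p(-hazard))
        dies_here = alive & (within < span)
        death_age[dies_here] = start + within[dies_here]
        alive &= ~dies_here
    death_age[alive] = 110  # hard cap
    dy = birth_years + death_age
    horizon = config.registry_window[1]
    return np.where(dy <= horizon, dy, np.nan)


def pedigree_links(persons: pd.DataFrame) -> pd.DataFrame:
    """Child -> parent link table (one row per non-founder)."""
    kids = persons.loc[~persons["is_founder"], ["person_id", "mother_id",
                                                "father_id", "family_id"]]
    return kids.rename(columns={"person_id": "child_id"}).reset_index(drop=True)


def assign_liabilities(
    persons: pd.DataFrame,
    h2: float,
    prevalence_K: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign additive + environmental liabilities and affection status.

    Founders draw their additive value from N(0, h2); each child receives the
    mid-parent mean plus Mendelian segregation noise N(0, h2/2), so that the
    additive variance stays h2 in every generation and first-degree pairs have
    liability correlation h2/2.  Environmental deviations are independent
    N(0, 1 - h2) for everyone — no shared environment.  A person is affected
    when liability exceeds ``t = Phi^{-1}(1 - K)``.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    rng = np.random.default_rng(seed)
    n = len(persons)
    ids = persons["person_id"].to_numpy()
    mother = persons["mother_id"].to_numpy()
    father = persons["father_id"].to_numpy()

    additive = np.full(n, np.nan)
    pos = {pid: i for i, pid in enumerate(ids)}
    is_founder = (mother < 0) & (father < 0)
    additive[is_founder] = rng.normal(0.0, np.sqrt(h2), size=is_founder.sum())

    remaining = np.flatnonzero(~is_founder)
    while remaining.size:
        m_idx = np.array([pos.get(m, -1) for m in mother[remaining]])
        f_idx = np.array([pos.get(f, -1) for f in father[remaining]])
        if (m_idx < 0).any() or (f_idx < 0).any():
            bad = ids[remaining[(m_idx < 0) | (f_idx < 0)]][:5]
            raise ValueError(f"missing parent rows for persons {list(bad)}")
        ready = ~np.isnan(additive[m_idx]) & ~np.isnan(additive[f_idx])
        if not ready.any():
            raise ValueError("pedigree contains a cycle")
        idx = remaining[ready]
        mid = (additive[m_idx[ready]] + additive[f_idx[ready]]) / 2.0
        additive[idx] = mid + rng.normal(
            0.0, np.sqrt(h2 / 2.0), size=idx.size
        )
        remaining = remaining[~ready]

    environment = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    liability = additive + environment
    t = stats.norm.isf(prevalence_K)
    return pd.DataFrame(
        {
            "person_id": ids,
            "additive_value": additive,
            "environment_value": environment,
            "liability": liability,
            "affected": liability > t,
        }
    )


def _date_in_year(year: int, rng: np.random.Generator) -> pd.Timestamp:
    return pd.Timestamp(
        year=int(year), month=int(rng.integers(1, 13)),
        day=int(rng.integers(1, 29)),
    )


def _icd_for(code10: str, year: int, switch: int) -> tuple[str, str]:
    """Era-appropriate (code, version) for an IIM patient's visit."""
    if year < switch:
        code9 = "710D" if code10 in ("M33.0", "M33.1") else "710E"
        return code9, "ICD9"
    return code10, "ICD10"


def generate_visit_records(
    persons: pd.DataFrame,
    liabilities: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit patient-register visit rows for the simulated population.

    Affected persons get a care sequence from a uniformly drawn onset age to
    death or the registry horizon, coded with ICD-9 myositis codes (710D/710E)
    before the era switch and ICD-10 (M33.x / G72.4) after, from the accepted
    specialist departments.  A configurable ``subthreshold_fraction`` of
    affected persons instead receive a single record that cannot satisfy the
    index case definition, to exercise ascertainment failure.  Persons may
    additionally carry background visits (non-IIM codes) and, at rate
    ``mimic_rate``, one muscular-dystrophy/metabolic-myopathy-coded visit.
    """
    rng = np.random.default_rng(
        (config.seed + 1) if seed is None else seed
    )
    win_lo, win_hi = config.registry_window
    switch = config.era_switch_year
    aff = liabilities.set_index("person_id")["affected"]
    depts = list(ACCEPTED_DEPARTMENTS)

    rows: list[tuple] = []

    def add(pid, year, code, main, setting, dept):
        code_v = _icd_for(code, year, switch) if code.startswith(("M33", "G72.4")) \
            else (code, "ICD9" if year < switch else "ICD10")
        rows.append(
            (pid, _date_in_year(year, rng), code_v[0], code_v[1],
             bool(main), setting, dept)
        )

    onset_lo, onset_hi = config.onset_age_range
    for person in persons.itertuples(index=False):
        pid = person.person_id
        death = person.death_year
        last_alive = int(death) if not np.isnan(death) else win_hi
        affected = bool(aff.get(pid, False))

        if affected:
            onset_age = int(rng.integers(onset_lo, onset_hi + 1))
            onset_year = person.birth_year + onset_age
            cap = min(last_alive, person.birth_year + 80)
            if onset_year > cap:
                onset_year = None  # liability never expressed before death
            if onset_year is not None:
                code10 = _subtype_code(onset_age, config, rng)
                start = max(onset_year, win_lo)
                end = min(last_alive, win_hi - 1)
                if start <= end:
                    if rng.random() < config.subthreshold_fraction:
                        _subthreshold_record(add, pid, start, end, code10,
                                             depts, rng)
                    else:
                        _care_sequence(add, pid, start, end, code10, config,
                                       depts, rng)

        if rng.random() < config.mimic_rate:
            year = int(rng.integers(
                max(person.birth_year, win_lo), max(last_alive, win_lo) + 1
            ))
            codes = DEFAULT_MIMIC_ICD9 if year < switch else DEFAULT_MIMIC_ICD10
            add(pid, year, codes[rng.integers(len(codes))], True,
                "inpatient" if year < 2001 else "outpatient",
                depts[int(rng.integers(len(depts)))])

        if rng.random() < config.background_visit_rate:
            year = int(rng.integers(
                max(person.birth_year, win_lo), max(last_alive, win_lo) + 1
            ))
            codes = _BACKGROUND_CODES_ICD9 if year < switch else _BACKGROUND_CODES
            add(pid, year, codes[int(rng.integers(len(codes)))],
                bool(rng.random() < 0.5),
                "inpatient" if year < 2001 else "outpatient",
                (depts + ["other"])[int(rng.integers(len(depts) + 1))])

    visits = pd.DataFrame(
        rows,
        columns=["person_id", "visit_date", "icd_code", "icd_version",
                 "main_diagnosis", "setting", "department"],
    )
    return visits.sort_values(["person_id", "visit_date"]).reset_index(drop=True)


def _subtype_code(onset_age: int, config: SimulationConfig,
                  rng: np.random.Generator) -> str:
    if onset_age <= 18:
        return "M33.0"
    if rng.random() < config.dm_fraction:
        return "M33.1"
    return ["M33.2", "M33.9", "G72.4"][int(rng.integers(3))]


def _care_sequence(add, pid, start, end, code10, config, depts, rng):
    """Regular IIM care visits, guaranteed to satisfy the case definition
    whenever the person is under care during the ascertainment windows."""
    era1_years = range(max(start, 1997), min(end, 2000) + 1)
    era2_years = range(max(start, 2001), min(end, 2016) + 1)
    for year in range(start, end + 1, config.visit_interval_years):
        setting = "inpatient" if year < 2001 else (
            "inpatient" if rng.random() < 0.3 else "outpatient"
        )
        add(pid, year, code10, rng.random() < 0.7, setting,
            depts[int(rng.integers(len(depts)))])
    if era1_years:
        add(pid, era1_years[0], code10, True, "inpatient",
            depts[int(rng.integers(len(depts)))])
    if era2_years:
        add(pid, era2_years[0], code10, True, "outpatient",
            depts[int(rng.integers(len(depts)))])
        add(pid, era2_years[-1], code10, rng.random() < 0.7, "outpatient",
            depts[int(rng.integers(len(depts)))])


def _subthreshold_record(add, pid, start, end, code10, depts, rng):
    """A single record that fails the index case definition on purpose."""
    era2_years = range(max(start, 2001), min(end, 2016) + 1)
    era1_years = range(max(start, 1997), min(end, 2000) + 1)
    dept = depts[int(rng.integers(len(depts)))]
    if era2_years:
        # one outpatient visit only: fails the era-2 ">= 2 visits" rule
        add(pid, era2_years[0], code10, True, "outpatient", dept)
    elif era1_years:
        # non-main diagnosis: fails the era-1 main-diagnosis rule
        add(pid, era1_years[0], code10, False, "inpatient", dept)
    else:
        # pre-1997 care only: outside both case-definition windows
        add(pid, start, code10, True, "inpatient", dept)


def simulate_registry(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedRegistry:
    """Run the full generator: pedigrees, liabilities, visit records."""
    base = config.seed if seed is None else seed
    persons = simulate_pedigrees(config, seed=base)
    liab = assign_liabilities(
        persons, config.h2, config.prevalence_K, seed=base + 1
    )
    visits = generate_visit_records(persons, liab, config, seed=base + 2)
    return SimulatedRegistry(
        persons=persons,
        pedigree=pedigree_links(persons),
        liabilities=liab,
        visits=visits,
        config=config,
    )


def write_registry(reg: SimulatedRegistry, outdir: str | Path) -> dict:
    """Write persons/pedigree/visits/liabilities CSVs plus a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg.persons.to_csv(outdir / "persons.csv", index=False)
    reg.pedigree.to_csv(outdir / "pedigree.csv", index=False)
    reg.liabilities.to_csv(outdir / "liabilities.csv", index=False)
    visits = reg.visits.copy()
    visits["visit_date"] = visits["visit_date"].dt.strftime("%Y-%m-%d")
    visits.to_csv(outdir / "visits.csv", index=False)
    reg.config.to_yaml(outdir / "config.yaml")
    cfg_text = (outdir / "config.yaml").read_text()
    manifest = {
        "seed": reg.config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_persons": int(len(reg.persons)),
        "n_visits": int(len(reg.visits)),
        "n_affected": int(reg.liabilities["affected"].sum()),
        "threshold": reg.threshold,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
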