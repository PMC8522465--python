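import numpy as np
import pandas as pd
import pytest

from famliab import SimulationConfig, simulate_registry


def make_visit(
    pid,
    date,
    code,
    main=True,
    setting="inpatient",
    dept="rheumatology",
    version=None,
):
    """One visit row with sensible defaults and era-consistent ICD version."""
    ts = pd.Timestamp(date)
    if version is None:
        version = "ICD9" if ts < pd.Timestamp("1997-01-01") else "ICD10"
    return {
        "person_id": pid,
        "visit_date": ts,
        "icd_code": code,
        "icd_version": version,
        "main_diagnosis": main,
        "setting": setting,
        "department": dept,
    }


def visits_frame(rows):
    return pd.DataFrame(rows)


def persons_frame(rows):
    """Persons table from dicts; fills defaults for optional columns."""
    defaults = {
        "family_id": 0,
        "sex": "female",
        "birth_year": 1950,
        "mother_id": -1,
        "father_id": -1,
        "region": 0,
        "is_founder": True,
        "birth_country": "domestic",
        "death_year": np.nan,
    }
    full = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(full)
    df["is_founder"] = (df["mother_id"] < 0) & (df["father_id"] < 0)
    return df


def two_child_families(n_families, birth_year=1950, seed=0):
    """Persons table of nuclear families with exactly two children each."""
    fam = np.arange(n_families)
    rows = {
        "person_id": np.arange(4 * n_families),
        "family_id": np.repeat(fam, 4),
        "mother_id": np.tile([-1, -1, 0, 0], n_families)
        + np.repeat(4 * fam, 4) * np.tile([0, 0, 1, 1], n_families),
        "father_id": np.tile([-1, -1, 1, 1], n_families)
        + np.repeat(4 * fam, 4) * np.tile([0, 0, 1, 1], n_families),
        "birth_year": np.tile([birth_year - 28, birth_year - 30,
                               birth_year, birth_year + 2], n_families),
    }
    df = pd.DataFrame(rows)
    df["sex"] = np.where(np.arange(len(df)) % 2 == 0, "female", "male")
    df["region"] = 0
    df["is_founder"] = df["mother_id"] < 0
    df["birth_country"] = "domestic"
    df["death_year"] = np.nan
    return df


@pytest.fixture(scope="session")
def small_registry():
    """A moderately sized simulated registry shared across tests.

    Uses a desk-scale prevalence (5%) so that ascertainment, matching and
    pairing all see non-trivial counts at 800 families.
    """
    cfg = SimulationConfig(
        n_families=800,
        prevalence_K=0.05,
        h2=0.5,
        seed=11,
        subthreshold_fraction=0.3,
        mimic_rate=0.02,
        birth_year_range=(1925, 1975),
    )
    return simulate_registry(cfg)
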