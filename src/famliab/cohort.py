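"""Matched family-cohort construction.

Builds the analysis cohort of a family-based case-comparator study: each
ascertained case is matched to up to five population comparators on sex,
birth year and region at the case's diagnosis date (risk-set sampling);
index persons pass an inclusion cascade (born domestically from 1932 on,
>= 1 first-degree relative alive in the exposure window); and every included
index contributes one row per first-degree relative (parent, full sibling,
offspring) with the relative's exposure status — the unit of the pair-level
analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotypes import RelativeExposureRule, exposure_flags

__all__ = [
    "first_degree_relatives",
    "match_comparators",
    "matched_sets_long",
    "apply_index_inclusion",
    "build_kinship_pairs",
    "describe_cohort",
]


def first_degree_relatives(persons: pd.DataFrame) -> pd.DataFrame:
    """All (index, relative, kinship) triples from the parental links.

    Full siblings must share both parents; each unordered sibling pair
    yields two rows (one per index role), and each parent-child link yields
    a ``parent`` row for the child and an ``offspring`` row for the parent.
    """
    kids = persons[~persons["is_founder"]]
    rows = []
    for parent_col in ("mother_id", "father_id"):
        links = kids[["person_id", parent_col]].rename(
            columns={"person_id": "index_id", parent_col: "relative_id"}
        )
        links = links[links["relative_id"] >= 0]
        rows.append(links.assign(kinship="parent"))
        rows.append(
            links.rename(
                columns={"index_id": "relative_id", "relative_id": "index_id"}
            ).assign(kinship="offspring")
        )
    sib_groups = kids.groupby(["mother_id", "father_id"])["person_id"]
    sib_rows = []
    for _, ids in sib_groups:
        arr = ids.to_numpy()
        if len(arr) > 1:
            a, b = np.meshgrid(arr, arr)
            mask = a != b
            sib_rows.append(
                pd.DataFrame(
                    {"index_id": a[mask], "relative_id": b[mask],
                     "kinship": "full_sibling"}
                )
            )
    if sib_rows:
        rows.append(pd.concat(sib_rows))
    out = pd.concat(rows, ignore_index=True)
    return out.drop_duplicates(["index_id", "relative_id"]).reset_index(drop=True)


def match_comparators(
    cases: pd.DataFrame,
    persons: pd.DataFrame,
    ratio: int = 5,
    seed: int = 0,
    reuse_across_sets: bool = True,
) -> pd.DataFrame:
    """Risk-set match each case to up to ``ratio`` comparators.

    Comparators share sex, birth year and region with their case, are alive
    at the match date (the case's diagnosis date) and are not themselves an
    ascertained case by that date.  Sampling is without replacement within a
    set; across sets reuse is allowed by default and can be disabled.
    Strata with fewer than ``ratio`` eligible persons keep whatever is
    available ("up to five"), including none.

    Returns one row per matched set with a ``comparator_ids`` list column.
    """
    if ratio < 1:
        raise ValueError(f"matching ratio must be >= 1, got {ratio}")
    rng = np.random.default_rng(seed)
    p = persons.set_index("person_id")
    dx_date = cases.set_index("person_id")["diagnosis_date"]

    strata: dict[tuple, np.ndarray] = {}
    key_cols = persons[["sex", "birth_year", "region"]].astype(object)
    for key, grp in persons.groupby(
        [key_cols["sex"], key_cols["birth_year"], key_cols["region"]],
        observed=True,
    ):
        strata[key] = grp["person_id"].to_numpy()

    used: set = set()
    sets = []
    ordered = cases.sort_values("person_id")
    for set_id, case in enumerate(ordered.itertuples(index=False)):
        cid = case.person_id
        match_date = case.diagnosis_date
        match_year = match_date.year
        key = (p.at[cid, "sex"], p.at[cid, "birth_year"], p.at[cid, "region"])
        pool = strata.get(key, np.array([], dtype=np.int64))
        eligible = []
        for pid in pool:
            if pid == cid:
                continue
            if not reuse_across_sets and pid in used:
                continue
            death = p.at[pid, "death_year"]
            if not np.isnan(death) and death < match_year:
                continue
            d = dx_date.get(pid)
            if d is not None and not pd.isna(d) and d <= match_date:
                continue
            eligible.append(pid)
        eligible = np.array(sorted(eligible), dtype=np.int64)
        k = min(ratio, len(eligible))
        chosen = (
            np.sort(rng.choice(eligible, size=k, replace=False))
            if k
            else np.array([], dtype=np.int64)
        )
        used.update(chosen.tolist())
        sets.append(
            {
                "set_id": set_id,
                "case_id": cid,
                "match_date": match_date,
                "sex": key[0],
                "birth_year": key[1],
                "region": key[2],
                "comparator_ids": chosen.tolist(),
            }
        )
    return pd.DataFrame(sets)


def matched_sets_long(sets: pd.DataFrame) -> pd.DataFrame:
    """Long format: one row per index person with ``is_case`` and ``set_id``."""
    rows = []
    for s in sets.itertuples(index=False):
        rows.append((s.set_id, s.case_id, True, s.match_date))
        for pid in s.comparator_ids:
            rows.append((s.set_id, pid, False, s.match_date))
    return pd.DataFrame(
        rows, columns=["set_id", "person_id", "is_case", "match_date"]
    )


def apply_index_inclusion(
    indexes: pd.DataFrame,
    persons: pd.DataFrame,
    alive_year: int = 1987,
    min_birth_year: int = 1932,
) -> tuple[pd.DataFrame, dict]:
    """Inclusion cascade for index persons.

    Drops indexes born abroad or before ``min_birth_year`` (parental links
    are unreliable for earlier cohorts), then indexes with no first-degree
    relative alive in the exposure window.  Returns the filtered table and an
    attrition-count dict, one entry per step.
    """
    p = persons.set_index("person_id")
    cascade = {"initial": int(len(indexes))}

    born = indexes[
        (indexes["person_id"].map(p["birth_year"]) >= min_birth_year)
        & (indexes["person_id"].map(p["birth_country"]).eq("domestic"))
    ]
    cascade["born_domestic_from_%d" % min_birth_year] = int(len(born))

    rels = first_degree_relatives(persons)
    death = p["death_year"]
    alive = rels["relative_id"].map(death)
    rels = rels[alive.isna() | (alive >= alive_year)]
    has_rel = born["person_id"].isin(set(rels["index_id"]))
    out = born[has_rel].reset_index(drop=True)
    cascade["with_relative_alive_%d" % alive_year] = int(len(out))
    return out, cascade


def build_kinship_pairs(
    indexes: pd.DataFrame,
    persons: pd.DataFrame,
    visits: pd.DataFrame,
    rule: RelativeExposureRule | None = None,
    alive_year: int = 1987,
) -> pd.DataFrame:
    """One row per (index, first-degree relative) pair with exposure status.

    ``indexes`` must carry ``person_id``, ``is_case`` and ``set_id`` columns
    (from :func:`matched_sets_long`).  Relatives must be alive in
    ``alive_year`` (1987 by default; 2001 in the late-register sensitivity
    variant).  ``family_id`` of the index person is the clustering key for
    robust variance estimation.
    """
    rule = rule or RelativeExposureRule()
    p = persons.set_index("person_id")
    rels = first_degree_relatives(persons)
    rels = rels[rels["index_id"].isin(set(indexes["person_id"]))]
    death = rels["relative_id"].map(p["death_year"])
    rels = rels[death.isna() | (death >= alive_year)].copy()

    flags = exposure_flags(visits, rule)
    exposed_ids = set(flags[flags].index)
    rels["exposed"] = rels["relative_id"].isin(exposed_ids)
    rels["relative_sex"] = rels["relative_id"].map(p["sex"])
    rels["relative_birth_year"] = rels["relative_id"].map(p["birth_year"])
    rels["family_id"] = rels["index_id"].map(p["family_id"])

    # an index person may anchor several matched sets (comparator reuse):
    # each appearance contributes its own pair rows
    meta_cols = ["person_id", "is_case"]
    if "set_id" in indexes.columns:
        meta_cols.append("set_id")
    meta = indexes[meta_cols].rename(
        columns={"person_id": "index_id", "is_case": "index_is_case"}
    )
    rels = rels.merge(meta, on="index_id", how="inner")
    rels["index_is_case"] = rels["index_is_case"].astype(bool)
    sort_cols = ["index_id", "relative_id"]
    if "set_id" in rels.columns:
        sort_cols = ["set_id"] + sort_cols
    return rels.sort_values(sort_cols).reset_index(drop=True)


def _median_q(series: pd.Series) -> str:
    q1, med, q3 = series.quantile([0.25, 0.5, 0.75])
    return f"{med:.0f} ({q1:.0f}-{q3:.0f})"


def describe_cohort(
    indexes: pd.DataFrame, persons: pd.DataFrame, pairs: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Descriptive tables of the index cohort and its family structure.

    Returns ``{"indexes": ..., "relatives": ...}``: counts and proportions of
    women, birth-year median (Q1-Q3) for index persons by case status, and
    per-kinship pair counts, relatives per family (mean +/- SD), proportion
    women and birth-year quartiles for relatives.
    """
    p = persons.set_index("person_id")
    idx = indexes.copy()
    idx["sex"] = idx["person_id"].map(p["sex"])
    idx["birth_year"] = idx["person_id"].map(p["birth_year"])

    rows = []
    for is_case, grp in idx.groupby("is_case"):
        n = len(grp)
        women = int((grp["sex"] == "female").sum())
        rows.append(
            {
                "group": "cases" if is_case else "comparators",
                "n": n,
                "women_n": women,
                "women_pct": round(100.0 * women / n) if n else np.nan,
                "birth_year_median_q1_q3": _median_q(grp["birth_year"]) if n else "",
            }
        )
    table_indexes = pd.DataFrame(rows)

    rows = []
    for (is_case, kinship), grp in pairs.groupby(
        ["index_is_case", "kinship"], observed=True
    ):
        per_family = grp.groupby("index_id").size()
        women = int((grp["relative_sex"] == "female").sum())
        rows.append(
            {
                "group": "cases" if is_case else "comparators",
                "kinship": kinship,
                "n_pairs": len(grp),
                "per_index_mean": per_family.mean(),
                "per_index_sd": per_family.std(ddof=1),
                "women_n": women,
                "women_pct": round(100.0 * women / len(grp)),
                "birth_year_median_q1_q3": _median_q(grp["relative_birth_year"]),
                "n_exposed": int(grp["exposed"].sum()),
            }
        )
    table_relatives = pd.DataFrame(rows)
    return {"indexes": table_indexes, "relatives": table_relatives}
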