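"""Matching, inclusion cascade, kinship pairs and descriptive tables."""

import numpy as np
import pandas as pd
import pytest

from famliab import (
    apply_index_inclusion,
    build_kinship_pairs,
    describe_cohort,
    match_comparators,
    matched_sets_long,
)
from famliab.cohort import first_degree_relatives

from conftest import make_visit, persons_frame, visits_frame


@pytest.fixture
def family():
    """Index 3 with two parents, one full sibling, one half-sibling, two kids."""
    return persons_frame(
        [
            {"person_id": 1, "sex": "female", "birth_year": 1925},  # mother
            {"person_id": 2, "sex": "male", "birth_year": 1922},    # father
            {"person_id": 9, "sex": "male", "birth_year": 1920},    # stepfather
            {"person_id": 3, "sex": "female", "birth_year": 1950,
             "mother_id": 1, "father_id": 2},                        # index
            {"person_id": 4, "sex": "male", "birth_year": 1952,
             "mother_id": 1, "father_id": 2},                        # full sib
            {"person_id": 5, "sex": "male", "birth_year": 1948,
             "mother_id": 1, "father_id": 9},                        # half sib
            {"person_id": 10, "sex": "male", "birth_year": 1949},    # partner
            {"person_id": 6, "sex": "female", "birth_year": 1975,
             "mother_id": 3, "father_id": 10},                       # child
            {"person_id": 7, "sex": "male", "birth_year": 1978,
             "mother_id": 3, "father_id": 10},                       # child
        ]
    )


class TestFirstDegreeRelatives:
    def test_counts_for_index_with_full_family(self, family):
        rels = first_degree_relatives(family)
        mine = rels[rels["index_id"] == 3]
        assert len(mine) == 5  # 2 parents + 1 full sibling + 2 offspring
        assert set(mine.loc[mine["kinship"] == "parent", "relative_id"]) == {1, 2}
        assert set(mine.loc[mine["kinship"] == "full_sibling",
                            "relative_id"]) == {4}
        assert set(mine.loc[mine["kinship"] == "offspring",
                            "relative_id"]) == {6, 7}

    def test_half_sibling_is_not_full_sibling(self, family):
        rels = first_degree_relatives(family)
        sibs = rels[rels["kinship"] == "full_sibling"]
        assert 5 not in set(sibs.loc[sibs["index_id"] == 3, "relative_id"])

    def test_pairs_unique_per_index(self, family):
        rels = first_degree_relatives(family)
        assert not rels.duplicated(["index_id", "relative_id"]).any()


class TestMatching:
    def _population(self, n_eligible):
        rows = [
            {"person_id": 0, "sex": "female", "birth_year": 1950, "region": 0}
        ]
        rows += [
            {"person_id": i + 1, "sex": "female", "birth_year": 1950,
             "region": 0}
            for i in range(n_eligible)
        ]
        # off-stratum persons must never be drawn
        rows += [
            {"person_id": 100 + i, "sex": "male", "birth_year": 1950,
             "region": 0}
            for i in range(10)
        ]
        return persons_frame(rows)

    def _cases(self):
        return pd.DataFrame(
            {"person_id": [0],
             "diagnosis_date": [pd.Timestamp("2005-06-01")]}
        )

    def test_full_stratum_draws_exactly_ratio(self):
        sets = match_comparators(self._cases(), self._population(10), ratio=5,
                                 seed=1)
        assert len(sets.iloc[0]["comparator_ids"]) == 5

    def test_small_stratum_takes_up_to_available(self):
        sets = match_comparators(self._cases(), self._population(3), ratio=5,
                                 seed=1)
        assert len(sets.iloc[0]["comparator_ids"]) == 3

    def test_same_seed_same_draw(self):
        a = match_comparators(self._cases(), self._population(10), seed=3)
        b = match_comparators(self._cases(), self._population(10), seed=3)
        assert a.iloc[0]["comparator_ids"] == b.iloc[0]["comparator_ids"]

    def test_exact_matching_contract(self, small_registry):
        from famliab import CaseDefinitionRule, ascertain_cases

        cases = ascertain_cases(small_registry.visits, CaseDefinitionRule())
        sets = match_comparators(cases, small_registry.persons, seed=5)
        p = small_registry.persons.set_index("person_id")
        for s in sets.itertuples(index=False):
            for pid in s.comparator_ids:
                assert p.at[pid, "sex"] == s.sex
                assert p.at[pid, "birth_year"] == s.birth_year
                assert p.at[pid, "region"] == s.region

    def test_dead_or_prior_case_excluded(self):
        persons = persons_frame(
            [
                {"person_id": 0, "birth_year": 1950},
                {"person_id": 1, "birth_year": 1950, "death_year": 2000.0},
                {"person_id": 2, "birth_year": 1950},
            ]
        )
        cases = pd.DataFrame(
            {
                "person_id": [0, 2],
                "diagnosis_date": [pd.Timestamp("2005-06-01"),
                                   pd.Timestamp("2003-01-01")],
            }
        )
        sets = match_comparators(cases, persons, ratio=5, seed=0)
        comps_for_0 = sets.loc[sets["case_id"] == 0, "comparator_ids"].iloc[0]
        assert comps_for_0 == []  # 1 died 2000, 2 was a case by 2005

    def test_ratio_validation(self):
        with pytest.raises(ValueError, match="ratio"):
            match_comparators(self._cases(), self._population(3), ratio=0)


class TestInclusion:
    def test_cascade(self):
        persons = persons_frame(
            [
                {"person_id": 1, "birth_year": 1930},  # too early
                {"person_id": 2, "birth_year": 1950,
                 "birth_country": "foreign"},
                {"person_id": 3, "birth_year": 1950},  # no relatives at all
                {"person_id": 4, "birth_year": 1955, "mother_id": 5,
                 "father_id": 6},
                {"person_id": 5, "birth_year": 1932, "death_year": 1980.0},
                {"person_id": 6, "birth_year": 1930, "death_year": 1990.0},
            ]
        )
        idx = pd.DataFrame({"person_id": [1, 2, 3, 4]})
        out, cascade = apply_index_inclusion(idx, persons, alive_year=1987)
        assert cascade["initial"] == 4
        assert cascade["born_domestic_from_1932"] == 2  # persons 3 and 4
        # person 3 has no relatives; person 4's father alive till 1990
        assert list(out["person_id"]) == [4]
        assert (
            cascade["initial"]
            >= cascade["born_domestic_from_1932"]
            >= cascade["with_relative_alive_1987"]
        )

    def test_all_relatives_dead_excluded(self):
        persons = persons_frame(
            [
                {"person_id": 4, "birth_year": 1955, "mother_id": 5,
                 "father_id": 6},
                {"person_id": 5, "birth_year": 1932, "death_year": 1980.0},
                {"person_id": 6, "birth_year": 1930, "death_year": 1985.0},
            ]
        )
        out, cascade = apply_index_inclusion(
            pd.DataFrame({"person_id": [4]}), persons, alive_year=1987
        )
        assert out.empty

    def test_empty_input(self):
        persons = persons_frame([{"person_id": 1}])
        out, cascade = apply_index_inclusion(
            pd.DataFrame({"person_id": []}), persons
        )
        assert out.empty
        assert cascade["initial"] == 0


class TestKinshipPairs:
    def test_pair_rows_and_sensitivity_variant(self, family):
        visits = visits_frame([make_visit(4, "1998-03-01", "M33.9")])
        indexes = pd.DataFrame(
            {"person_id": [3], "is_case": [True], "set_id": [0]}
        )
        pairs = build_kinship_pairs(indexes, family, visits, alive_year=1987)
        assert len(pairs) == 5
        assert pairs.loc[pairs["relative_id"] == 4, "exposed"].iloc[0]
        assert not pairs.loc[pairs["relative_id"] != 4, "exposed"].any()

    def test_alive_year_2001_drops_mid_90s_death(self, family):
        family = family.copy()
        family.loc[family["person_id"] == 1, "death_year"] = 1995.0
        indexes = pd.DataFrame(
            {"person_id": [3], "is_case": [True], "set_id": [0]}
        )
        visits = visits_frame([make_visit(4, "1998-03-01", "M33.9")])
        pairs87 = build_kinship_pairs(indexes, family, visits, alive_year=1987)
        pairs01 = build_kinship_pairs(indexes, family, visits, alive_year=2001)
        assert 1 in set(pairs87["relative_id"])
        assert 1 not in set(pairs01["relative_id"])
        assert len(pairs01) == len(pairs87) - 1

    def test_pair_counts_sum_over_indexes(self, small_registry):
        from famliab import CaseDefinitionRule, ascertain_cases

        cases = ascertain_cases(small_registry.visits, CaseDefinitionRule())
        sets = match_comparators(cases, small_registry.persons, seed=5)
        members = matched_sets_long(sets)
        pairs = build_kinship_pairs(members.assign(is_case=members["is_case"]),
                                    small_registry.persons,
                                    small_registry.visits)
        per_index = pairs.groupby(["set_id", "index_id"]).size()
        assert per_index.sum() == len(pairs)


class TestDescribe:
    def test_hand_checked_summaries(self, family):
        indexes = pd.DataFrame(
            {"person_id": [3, 4], "is_case": [True, False], "set_id": [0, 0]}
        )
        visits = visits_frame([make_visit(6, "2005-03-01", "M33.9",
                                          setting="outpatient")])
        pairs = build_kinship_pairs(indexes, family, visits)
        tables = describe_cohort(indexes, family, pairs)
        idx_tab = tables["indexes"].set_index("group")
        assert idx_tab.loc["cases", "n"] == 1
        assert idx_tab.loc["cases", "women_pct"] == 100
        assert idx_tab.loc["comparators", "women_pct"] == 0
        rel_tab = tables["relatives"]
        case_parents = rel_tab[
            (rel_tab["group"] == "cases") & (rel_tab["kinship"] == "parent")
        ].iloc[0]
        assert case_parents["n_pairs"] == 2
        # parents born 1925 and 1922 -> median 1923.5
        assert case_parents["birth_year_median_q1_q3"].startswith("1924")

    def test_all_female_pairs(self, family):
        indexes = pd.DataFrame(
            {"person_id": [7], "is_case": [True], "set_id": [0]}
        )
        visits = visits_frame([make_visit(6, "2005-03-01", "M33.9")])
        pairs = build_kinship_pairs(indexes, family, visits)
        mothers = pairs[pairs["relative_id"] == 3]
        assert (mothers["relative_sex"] == "female").all()
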