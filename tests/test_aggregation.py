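"""Odds-ratio estimators: conditional likelihood, sandwich variance, tables."""

import math

import numpy as np
import pandas as pd
import pytest

from famliab import (
    ConditionalLogisticAggregation,
    PairLevelAggregation,
    build_pair_table,
    fit_conditional_logistic,
)
from famliab.aggregation import SingularDesignError, conditional_loglik


def make_sets(set_specs):
    """Long matched-set table from (case_exposed, n_exposed_comp, n_comp)."""
    rows = []
    for sid, (xc, ne, n_comp) in enumerate(set_specs):
        rows.append((sid, True, bool(xc)))
        for j in range(n_comp):
            rows.append((sid, False, j < ne))
    return pd.DataFrame(rows, columns=["set_id", "is_case", "exposed"])


def pairs_from_counts(a, b, c, d):
    """Pair table rows reproducing a 2x2 of case/comparator pair counts."""
    n = a + b + c + d
    df = pd.DataFrame(
        {
            "index_is_case": [True] * (a + b) + [False] * (c + d),
            "exposed": [True] * a + [False] * b + [True] * c + [False] * d,
            "kinship": "full_sibling",
        }
    )
    df["family_id"] = np.arange(n)
    df["set_id"] = np.arange(n)
    df["index_id"] = np.arange(n)
    return df


class TestConditionalLogistic:
    def test_single_set_exposed_case_is_separated(self):
        df = make_sets([(1, 0, 5)])
        est = ConditionalLogisticAggregation().fit(
            df["exposed"], df["is_case"], df["set_id"]
        )
        assert est.separated_
        assert est.result_.estimate == math.inf
        assert est.result_.ci_high == math.inf

    def test_constant_exposure_raises(self):
        df = make_sets([(1, 5, 5), (1, 5, 5)])  # everyone exposed
        with pytest.raises(ValueError, match="informative"):
            ConditionalLogisticAggregation().fit(
                df["exposed"], df["is_case"], df["set_id"]
            )

    def test_mle_matches_grid_search_oracle(self):
        """Newton solution equals brute-force maximisation of the exact
        conditional likelihood on a toy collection of sets."""
        specs = [(1, 1, 5), (0, 2, 5), (1, 0, 4), (0, 1, 3), (1, 2, 5)]
        df = make_sets(specs)
        est = ConditionalLogisticAggregation().fit(
            df["exposed"], df["is_case"], df["set_id"]
        )
        grid = np.linspace(-4, 4, 200001)
        lls = [conditional_loglik(b, df["exposed"], df["is_case"],
                                  df["set_id"]) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert abs(est.coef_ - beta_grid) < 1e-4  # grid resolution 4e-5
        # refine with a local quadratic step to reach the oracle's true max
        from scipy.optimize import minimize_scalar

        refined = minimize_scalar(
            lambda b: -conditional_loglik(b, df["exposed"], df["is_case"],
                                          df["set_id"]),
            bracket=(beta_grid - 1e-3, beta_grid + 1e-3),
            method="brent", options={"xtol": 1e-12},
        ).x
        assert abs(est.coef_ - refined) < 1e-6

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(4)
        specs = [
            (int(rng.random() < 0.5), int(rng.integers(0, 4)), 5)
            for _ in range(40)
        ]
        df = make_sets(specs)
        est = ConditionalLogisticAggregation().fit(
            df["exposed"], df["is_case"], df["set_id"]
        )
        sm_fit = ConditionalLogit(
            df["is_case"].astype(float).to_numpy(),
            df["exposed"].astype(float).to_numpy()[:, None],
            groups=df["set_id"].to_numpy(),
        ).fit(disp=0)
        # statsmodels' BFGS stops at a looser gradient tolerance than the
        # Newton solver, so agreement is to its convergence accuracy
        assert abs(est.coef_ - sm_fit.params[0]) < 1e-4
        assert abs(est.se_ - sm_fit.bse[0]) < 1e-4

    def test_coverage_under_known_odds_ratio(self):
        """Wald CIs from sets generated at OR=4 cover the truth ~95%."""
        rng = np.random.default_rng(12)
        beta = math.log(4.0)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            x = (rng.random((3000, 6)) < 0.08).astype(float)
            w = np.exp(beta * x)
            pick = (w.cumsum(1) / w.sum(1, keepdims=True)) > rng.random(
                (3000, 1)
            )
            case_idx = pick.argmax(1)
            rows = []
            for sid in range(3000):
                for j in range(6):
                    rows.append((sid, j == case_idx[sid], bool(x[sid, j])))
            df = pd.DataFrame(rows, columns=["set_id", "is_case", "exposed"])
            r = fit_conditional_logistic(df)
            if r.ci_low <= 4.0 <= r.ci_high:
                hits += 1
        assert hits >= 33  # ~95% nominal; binomial slack at 40 replicates


class TestPairLevelModel:
    def test_no_covariates_equals_crude_or(self):
        pairs = pairs_from_counts(13, 7602, 16, 37293)
        est = PairLevelAggregation(variant="covariate_adjusted").fit(pairs)
        crude = (13 * 37293) / (7602 * 16)
        assert abs(est.result_.estimate - crude) < 1e-6

    def test_singleton_clusters_match_hc_robust(self):
        import statsmodels.api as sm

        pairs = pairs_from_counts(20, 180, 35, 365)
        est = PairLevelAggregation(variant="covariate_adjusted").fit(pairs)
        X = sm.add_constant(pairs["exposed"].astype(float))
        hc = sm.Logit(pairs["index_is_case"].astype(float), X).fit(
            disp=0, cov_type="HC1"
        )
        assert np.isclose(est.se_, hc.bse.iloc[1], rtol=5e-3)

    def test_duplication_invariance_of_clustered_sandwich(self):
        pairs = pairs_from_counts(20, 180, 35, 365)
        doubled = pd.concat([pairs, pairs], ignore_index=True)
        a = PairLevelAggregation(variant="covariate_adjusted").fit(pairs)
        b = PairLevelAggregation(variant="covariate_adjusted").fit(doubled)
        assert np.isclose(a.coef_, b.coef_, atol=1e-8)
        # same clusters, doubled rows: sandwich unchanged up to the
        # finite-sample correction factor
        assert np.isclose(a.se_, b.se_, rtol=5e-3)

    def test_conditional_variant_close_to_adjusted_on_matched_data(self):
        rng = np.random.default_rng(7)
        rows = []
        fam = 0
        for sid in range(400):
            for is_case in [True] + [False] * 3:
                n_rel = rng.integers(1, 4)
                p = 0.25 if is_case else 0.10
                for _ in range(n_rel):
                    rows.append(
                        (sid, fam, is_case, rng.random() < p,
                         rng.integers(1920, 1980))
                    )
                fam += 1
        pairs = pd.DataFrame(
            rows,
            columns=["set_id", "family_id", "index_is_case", "exposed",
                     "relative_birth_year"],
        )
        cond = PairLevelAggregation(variant="conditional").fit(pairs)
        adj = PairLevelAggregation(variant="covariate_adjusted").fit(pairs)
        assert abs(math.log(cond.result_.estimate)
                   - math.log(adj.result_.estimate)) < 0.2

    def test_singular_design_names_columns(self):
        pairs = pairs_from_counts(5, 45, 5, 95)
        pairs["dup"] = pairs["exposed"].astype(float)
        with pytest.raises(SingularDesignError, match="dup"):
            PairLevelAggregation(
                covariates=["dup"], variant="covariate_adjusted"
            ).fit(pairs)


class TestPairTable:
    def test_symmetric_table_gives_unit_or(self):
        pairs = pairs_from_counts(10, 90, 10, 90)
        t = build_pair_table(pairs)
        assert t.odds_ratio == 1.0

    def test_published_count_tables(self):
        any_fdr = build_pair_table(pairs_from_counts(13, 7602, 16, 37293))
        assert round(any_fdr.odds_ratio, 2) == 3.99
        sib = build_pair_table(pairs_from_counts(9, 2455, 10, 11675),
                               kinship="full_sibling")
        assert round(sib.odds_ratio, 2) == 4.28

    def test_zero_cell_is_flagged_not_corrected(self):
        t = build_pair_table(pairs_from_counts(0, 100, 5, 95))
        assert t.a == 0.0
        assert math.isnan(t.odds_ratio) or t.odds_ratio == 0.0

    def test_null_simulation_crude_or_covers_one(self):
        """With h2=0, sibling affection is independent: the crude pair OR's
        95% CI covers 1 in nearly all replicates."""
        from famliab import assign_liabilities
        from conftest import two_child_families

        hits = 0
        n_rep = 20
        persons = two_child_families(8000)
        kid_rows = persons.index[persons["mother_id"] >= 0]
        for rep in range(n_rep):
            liab = assign_liabilities(persons, h2=0.0, prevalence_K=0.05,
                                      seed=100 + rep)
            aff = liab["affected"].to_numpy()
            s1, s2 = aff[kid_rows[0::2]], aff[kid_rows[1::2]]
            # double-entered sibling pair table
            a = int((s1 & s2).sum()) * 2
            b = int((s1 & ~s2).sum()) + int((~s1 & s2).sum())
            c = b
            d = int((~s1 & ~s2).sum()) * 2
            or_ = (a * d) / (b * c)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            lo = math.exp(math.log(or_) - 1.96 * se)
            hi = math.exp(math.log(or_) + 1.96 * se)
            if lo <= 1.0 <= hi:
                hits += 1
        assert hits >= 17
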