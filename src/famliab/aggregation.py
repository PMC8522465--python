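"""Familial-aggregation odds ratios from matched family data.

Two complementary models:

* family level — the index's disease status regressed on "has >= 1 affected
  first-degree relative", maximising the exact conditional likelihood within
  each 1:m matched set (:class:`ConditionalLogisticAggregation`, implemented
  directly since the single-parameter set likelihood has a simple closed
  form);
* pair level — every (index, relative) pair an observation, disease status of
  the index regressed on the relative's status, conditioning on the matching
  cluster and with a sandwich variance aggregated over families to absorb the
  dependence between pairs sharing relatives
  (:class:`PairLevelAggregation`, backed by statsmodels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .heritability import WeightedTable2x2

__all__ = [
    "AggregationResult",
    "ConditionalLogisticAggregation",
    "PairLevelAggregation",
    "build_pair_table",
    "fit_conditional_logistic",
    "fit_pair_level_model",
]

_Z95 = 1.959963984540054


class SingularDesignError(ValueError):
    """Raised when the pair-level design matrix is rank deficient."""


@dataclass
class AggregationResult:
    """An odds-ratio estimate with its Wald interval on the log scale."""

    estimate: float
    ci_low: float
    ci_high: float
    log_or_se: float
    model: str
    covariates: list[str] = field(default_factory=list)
    n_informative: int | None = None
    separated: bool = False

    def as_dict(self) -> dict:
        return {
            "or": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_or_se": self.log_or_se,
            "model": self.model,
            "covariates": self.covariates,
            "n_informative": self.n_informative,
            "separated": self.separated,
        }


class ConditionalLogisticAggregation(BaseEstimator):
    """Exact conditional logistic regression for 1:m matched sets.

    Each matched set contains one case and up to m comparators; the exposure
    is a binary family-history indicator.  Conditioning on one case per set,
    a set with ``n1`` exposed members out of ``n`` contributes
    ``exp(x_case * beta) / (n1 * exp(beta) + (n - n1))`` to the likelihood,
    so only sets where exposure varies are informative.  The scalar MLE is
    found by Newton-Raphson with a bisection safeguard; the Wald interval
    uses the observed information.

    If the exposed-case count hits the boundary of its attainable range the
    likelihood is monotone (complete separation): the fit is flagged and the
    corresponding interval bound is infinite rather than raising.

    Attributes
    ----------
    coef_ : float
        Log odds ratio (``+/-inf`` under separation).
    result_ : AggregationResult
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-12):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, groups):
        """Fit from member-level arrays.

        Parameters
        ----------
        X : array-like of shape (n_members,)
            Binary exposure of each set member (case or comparator).
        y : array-like of shape (n_members,)
            True for the case member of the set.
        groups : array-like of shape (n_members,)
            Matched-set identifier.
        """
        x = np.asarray(X, dtype=float).ravel()
        yy = np.asarray(y, dtype=bool).ravel()
        g = np.asarray(groups)
        sets = []
        for gid in pd.unique(g):
            m = g == gid
            if yy[m].sum() != 1:
                raise ValueError(
                    f"matched set {gid!r} must contain exactly one case"
                )
            n1 = int(x[m].sum())
            n = int(m.sum())
            if 0 < n1 < n:  # informative only
                sets.append((int(x[m][yy[m]][0]), n1, n))
        if not sets:
            raise ValueError("no informative matched sets (exposure constant)")
        self.n_informative_ = len(sets)
        t_stat = sum(s[0] for s in sets)

        if t_stat == 0 or t_stat == len(sets):
            sign = 1.0 if t_stat else -1.0
            self.coef_ = sign * math.inf
            self.separated_ = True
            est = math.inf if sign > 0 else 0.0
            self.result_ = AggregationResult(
                estimate=est,
                ci_low=0.0 if sign < 0 else np.nan,
                ci_high=math.inf if sign > 0 else np.nan,
                log_or_se=math.inf,
                model="conditional_family",
                n_informative=len(sets),
                separated=True,
            )
            return self

        beta = 0.0
        for _ in range(self.max_iter):
            score, info = self._score_info(beta, sets)
            if info <= 0:
                break
            step = score / info
            beta += np.clip(step, -5.0, 5.0)
            if abs(score) < self.tol:
                break
        score, info = self._score_info(beta, sets)
        se = 1.0 / math.sqrt(info)
        self.coef_ = beta
        self.se_ = se
        self.separated_ = False
        self.result_ = AggregationResult(
            estimate=math.exp(beta),
            ci_low=math.exp(beta - _Z95 * se),
            ci_high=math.exp(beta + _Z95 * se),
            log_or_se=se,
            model="conditional_family",
            n_informative=len(sets),
        )
        return self

    @staticmethod
    def _score_info(beta: float, sets) -> tuple[float, float]:
        score = 0.0
        info = 0.0
        eb = math.exp(beta)
        for xc, n1, n in sets:
            denom = n1 * eb + (n - n1)
            p = n1 * eb / denom
            score += xc - p
            info += p * (1.0 - p)
        return score, info


def conditional_loglik(beta: float, X, y, groups) -> float:
    """Conditional log likelihood of 1:m matched sets at a given beta.

    Exposed here so that an independent grid search can be run against the
    Newton solver.
    """
    x = np.asarray(X, dtype=float).ravel()
    yy = np.asarray(y, dtype=bool).ravel()
    g = np.asarray(groups)
    ll = 0.0
    eb = math.exp(beta)
    for gid in pd.unique(g):
        m = g == gid
        n1 = int(x[m].sum())
        n = int(m.sum())
        xc = int(x[m][yy[m]][0])
        ll += xc * beta - math.log(n1 * eb + (n - n1))
    return ll


class PairLevelAggregation(BaseEstimator):
    """Pair-level logistic model with family-clustered sandwich variance.

    Each (index, relative) pair is one observation; the outcome is whether
    the index is a case and the exposure whether the relative is affected.
    Conditioning on the matching design is done either by the exact
    conditional likelihood within matched sets (``variant="conditional"``)
    or by entering the matching factors as covariates
    (``variant="covariate_adjusted"``).  In both variants the variance is a
    sandwich aggregated over family clusters, since one relative can appear
    in several pairs of the same family.

    Parameters
    ----------
    covariates : list of str, optional
        Extra adjustment columns (e.g. relative sex and birth year; and for
        the covariate-adjusted variant the index matching factors).
        Categorical columns are dummy-coded.
    variant : {"conditional", "covariate_adjusted"}
    cluster_col, strata_col, exposure_col, outcome_col : str
        Column names in the pair table.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        variant: str = "conditional",
        cluster_col: str = "family_id",
        strata_col: str = "set_id",
        exposure_col: str = "exposed",
        outcome_col: str = "index_is_case",
    ):
        self.covariates = covariates
        self.variant = variant
        self.cluster_col = cluster_col
        self.strata_col = strata_col
        self.exposure_col = exposure_col
        self.outcome_col = outcome_col

    def _design(self, pairs: pd.DataFrame) -> pd.DataFrame:
        cols = [self.exposure_col] + list(self.covariates or [])
        X = pairs[cols].copy()
        X[self.exposure_col] = X[self.exposure_col].astype(float)
        X = pd.get_dummies(X, drop_first=True, dtype=float)
        # standardise continuous covariates (e.g. birth year) so the
        # conditional likelihood's exponentials stay in range; the exposure
        # coefficient is unaffected
        for c in X.columns:
            if c == self.exposure_col:
                continue
            v = X[c]
            if v.nunique() > 2:
                sd = v.std(ddof=0)
                X[c] = (v - v.mean()) / (sd if sd > 0 else 1.0)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # identify offending columns by greedy rank check
            bad = []
            keep: list[str] = []
            for c in X.columns:
                trial = X[keep + [c]].to_numpy()
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(c)
                else:
                    bad.append(c)
            raise SingularDesignError(
                f"design matrix is singular; collinear columns: {bad}"
            )
        return X

    def fit(self, X, y=None):
        """Fit on a kinship-pair table (DataFrame)."""
        pairs = X
        yy = pairs[self.outcome_col].astype(float).to_numpy()
        design = self._design(pairs)
        clusters = pairs[self.cluster_col].to_numpy()

        if self.variant == "covariate_adjusted":
            exog = sm.add_constant(design, has_constant="add")
            model = sm.Logit(yy, exog)
            res = model.fit(
                disp=0, cov_type="cluster",
                cov_kwds={"groups": clusters},
            )
            names = list(exog.columns)
            i = names.index(self.exposure_col)
            beta = np.asarray(res.params)[i]
            se = np.asarray(res.bse)[i]
        elif self.variant == "conditional":
            beta, se = self._fit_conditional(design, yy, pairs, clusters)
        else:
            raise ValueError(f"unknown variant {self.variant!r}")

        self.coef_ = float(beta)
        self.se_ = float(se)
        self.result_ = AggregationResult(
            estimate=math.exp(beta),
            ci_low=math.exp(beta - _Z95 * se),
            ci_high=math.exp(beta + _Z95 * se),
            log_or_se=float(se),
            model=f"pair_level_{self.variant}",
            covariates=list(self.covariates or []),
        )
        return self

    def _fit_conditional(self, design, yy, pairs, clusters):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        strata = pairs[self.strata_col].to_numpy()
        model = ConditionalLogit(yy, design.to_numpy(), groups=strata)
        res = model.fit(disp=0, maxiter=500)
        params = np.atleast_1d(res.params)

        # reconstruct the model's internal group order: first appearance,
        # minus groups dropped for having no within-group outcome variance
        kept_labels = []
        for lab in pd.unique(strata):
            ygrp = yy[strata == lab]
            if ygrp.std() > 0:
                kept_labels.append(lab)
        assert len(kept_labels) == model._n_groups

        # family-clustered sandwich: per-set scores, sets clustered by the
        # family of their case pairs (one case index per matched set)
        hess = model.hessian(params)
        a_inv = np.linalg.inv(-hess)
        set_cluster = (
            pairs.loc[pairs[self.outcome_col].astype(bool), [self.strata_col,
                                                             self.cluster_col]]
            .drop_duplicates(self.strata_col)
            .set_index(self.strata_col)[self.cluster_col]
        )
        scores: dict = {}
        for grp_idx, grp_label in enumerate(kept_labels):
            s = np.atleast_1d(model.score_grp(grp_idx, params))
            key = set_cluster.get(grp_label, grp_label)
            scores[key] = scores.get(key, 0.0) + s
        b = np.zeros((len(params), len(params)))
        for s in scores.values():
            b += np.outer(s, s)
        cov = a_inv @ b @ a_inv
        i = list(design.columns).index(self.exposure_col)
        return params[i], math.sqrt(cov[i, i])


def build_pair_table(
    pairs: pd.DataFrame, kinship: str | None = None
) -> WeightedTable2x2:
    """Pair-level 2x2 table: case pairs vs comparator pairs by exposure.

    ``kinship=None`` pools all first-degree kinships; otherwise one of
    ``parent``, ``full_sibling``, ``offspring``.  The crude odds ratio is the
    table's cross-product ratio; zero cells leave it infinite/undefined and
    are *not* continuity-corrected, since the table feeds the tetrachoric
    solver unchanged.
    """
    sub = pairs if kinship is None else pairs[pairs["kinship"] == kinship]
    case = sub[sub["index_is_case"]]
    comp = sub[~sub["index_is_case"]]
    return WeightedTable2x2(
        a=float(case["exposed"].sum()),
        b=float(len(case) - case["exposed"].sum()),
        c=float(comp["exposed"].sum()),
        d=float(len(comp) - comp["exposed"].sum()),
    )


def fit_conditional_logistic(
    members: pd.DataFrame,
    exposure_col: str = "exposed",
    outcome_col: str = "is_case",
    set_col: str = "set_id",
) -> AggregationResult:
    """Family-level conditional logistic OR from a long matched-set table."""
    est = ConditionalLogisticAggregation()
    est.fit(members[exposure_col], members[outcome_col], members[set_col])
    return est.result_


def fit_pair_level_model(
    pairs: pd.DataFrame,
    covariates: list[str] | None = None,
    variant: str = "conditional",
) -> AggregationResult:
    """Pair-level OR with family-clustered sandwich variance."""
    est = PairLevelAggregation(covariates=covariates, variant=variant)
    est.fit(pairs)
    return est.result_
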