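"""Liability-threshold heritability from pair-level affection data.

The disease is modelled as a dichotomisation of a latent standard-normal
liability: a person is affected when liability exceeds the threshold
``t = Phi^{-1}(1 - K)`` set by the population prevalence ``K``.  For a pair of
relatives the two liabilities are bivariate normal with correlation ``rho``;
under a purely additive genetic model ``rho = r * h2`` where ``r`` is the
degree of relatedness (0.5 for first-degree relatives), so the narrow-sense
heritability is estimated as the tetrachoric correlation of the 2x2
affection-status table divided by the relatedness.

Because the comparator families are a subsample of the population while the
case families are a census, the observed pair table over-represents affected
indexes.  :func:`reweight_to_population` rebuilds a population-representative
table by up-weighting the comparator rows until the index-affected margin
equals the assumed population prevalence; the reweighting preserves
within-row proportions and hence the observed odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "WeightedTable2x2",
    "TetrachoricFit",
    "bivariate_normal_upper_tail",
    "reweight_to_population",
    "solve_tetrachoric",
    "estimate_heritability",
    "prevalence_sweep",
    "TetrachoricHeritability",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

# Gauss-Legendre abscissae/weights used by Genz's bivariate-normal algorithm.
_GL_RULES = (
    (
        np.array([0.1713244923791704, 0.3607615730481386, 0.4679139345726910]),
        np.array([0.9324695142031521, 0.6612093864662645, 0.2386191860831969]),
    ),
    (
        np.array(
            [
                0.04717533638651183, 0.1069393259953184, 0.1600783285433462,
                0.2031674267230659, 0.2334925365383548, 0.2491470458134028,
            ]
        ),
        np.array(
            [
                0.9815606342467192, 0.9041172563704749, 0.7699026741943047,
                0.5873179542866175, 0.3678314989981802, 0.1252334085114689,
            ]
        ),
    ),
    (
        np.array(
            [
                0.01761400713915212, 0.04060142980038694, 0.06267204833410907,
                0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                0.1316886384491766, 0.1420961093183820, 0.1491729864726037,
                0.1527533871307258,
            ]
        ),
        np.array(
            [
                0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                0.5108670019508271, 0.3737060887154195, 0.2277858511416451,
                0.07652652113349734,
            ]
        ),
    ),
)


def _phi(x: float) -> float:
    """Standard normal lower CDF."""
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def bivariate_normal_upper_tail(t1: float, t2: float, rho: float) -> float:
    """P(X1 > t1, X2 > t2) for a standard bivariate normal with correlation rho.

    Uses Genz's hybrid algorithm: Gauss-Legendre quadrature on the Drezner-
    Wesolowsky arcsine transform for moderate ``|rho|``, and an asymptotic
    expansion plus quadrature near ``|rho| = 1``.  Absolute accuracy is of
    order 1e-15, well inside the 1e-10 the tetrachoric solver needs.

    Parameters
    ----------
    t1, t2 : float
        Thresholds on the two liability axes.
    rho : float
        Latent correlation, must satisfy ``|rho| < 1``.
    """
    if not abs(rho) < 1:
        raise ValueError(f"correlation must satisfy |rho| < 1, got {rho}")
    h = float(t1)
    k = float(t2)
    r = float(rho)
    hk = h * k
    bvn = 0.0
    if abs(r) < 0.3:
        w, x = _GL_RULES[0]
    elif abs(r) < 0.75:
        w, x = _GL_RULES[1]
    else:
        w, x = _GL_RULES[2]

    if abs(r) < 0.925:
        if r != 0.0:
            hs = (h * h + k * k) / 2.0
            asr = math.asin(r)
            for wi, xi in zip(w, x):
                for sgn in (-1.0, 1.0):
                    sn = math.sin(asr * (sgn * xi + 1.0) / 2.0)
                    bvn += wi * math.exp((sn * hk - hs) / (1.0 - sn * sn))
            bvn *= asr / (4.0 * math.pi)
        bvn += _phi(-h) * _phi(-k)
        return bvn

    if r < 0.0:
        k = -k
        hk = -hk
    as_ = (1.0 - r) * (1.0 + r)
    a = math.sqrt(as_)
    bs = (h - k) ** 2
    c = (4.0 - hk) / 8.0
    d = (12.0 - hk) / 16.0
    asr = -(bs / as_ + hk) / 2.0
    if asr > -100.0:
        bvn = a * math.exp(asr) * (
            1.0 - c * (bs - as_) * (1.0 - d * bs / 5.0) / 3.0
            + c * d * as_ * as_ / 5.0
        )
    if -hk < 100.0:
        b = math.sqrt(bs)
        bvn -= (
            math.exp(-hk / 2.0) * _SQRT_2PI * _phi(-b / a) * b
            * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0)
        )
    a /= 2.0
    for wi, xi in zip(w, x):
        for sgn in (-1.0, 1.0):
            xs = (a * (sgn * xi + 1.0)) ** 2
            rs = math.sqrt(1.0 - xs)
            asr = -(bs / xs + hk) / 2.0
            if asr > -100.0:
                bvn += (
                    a * wi * math.exp(asr)
                    * (
                        math.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                        - (1.0 + c * xs * (1.0 + d * xs))
                    )
                )
    bvn = -bvn / (2.0 * math.pi)
    if r > 0.0:
        bvn += _phi(-max(h, k))
    else:
        bvn = -bvn
        if k > h:
            bvn += _phi(k) - _phi(h)
    return max(bvn, 0.0)


def _bvn_density(t1: float, t2: float, rho: float) -> float:
    """Standard bivariate normal density at (t1, t2)."""
    det = 1.0 - rho * rho
    q = (t1 * t1 - 2.0 * rho * t1 * t2 + t2 * t2) / det
    return math.exp(-q / 2.0) / (2.0 * math.pi * math.sqrt(det))


@dataclass
class WeightedTable2x2:
    """Pair-level 2x2 contingency table with (possibly non-integer) cell masses.

    Rows index the index person's affection status (row 1 = affected case),
    columns the relative's exposure status (column 1 = relative affected).
    Cell masses may carry population weights from ascertainment correction.
    """

    a: float  # index affected, relative affected
    b: float  # index affected, relative unaffected
    c: float  # index unaffected, relative affected
    d: float  # index unaffected, relative unaffected

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell masses must be non-negative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def row1_margin(self) -> float:
        """Probability that the index member of a pair is affected."""
        return (self.a + self.b) / self.total

    @property
    def col1_margin(self) -> float:
        """Probability that the relative member of a pair is affected."""
        return (self.a + self.c) / self.total

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class TetrachoricFit:
    """Result of a tetrachoric heritability fit."""

    rho: float
    t_index: float
    t_relative: float
    se_rho: float
    relatedness: float
    assumed_K: float | None
    n_effective: float
    h2: float = field(init=False)
    ci: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.h2 = self.rho / self.relatedness
        half = 1.96 * self.se_rho
        self.ci = (
            (self.rho - half) / self.relatedness,
            (self.rho + half) / self.relatedness,
        )

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "se_rho": self.se_rho,
            "t_index": self.t_index,
            "t_relative": self.t_relative,
            "relatedness": self.relatedness,
            "assumed_K": self.assumed_K,
            "n_effective": self.n_effective,
            "h2": self.h2,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
        }


def reweight_to_population(
    case_pairs: tuple[float, float],
    comparator_pairs: tuple[float, float],
    assumed_K: float,
    mode: str = "cases_census",
) -> WeightedTable2x2:
    """Rebuild a population-representative pair table from an ascertained sample.

    Case pairs are a census of the affected population, so they keep weight 1;
    comparator pairs are up-weighted by the single factor that makes the
    index-affected margin of the table equal ``assumed_K``.  Because every row
    is scaled uniformly, within-row proportions — and therefore the odds
    ratio — are unchanged.

    Parameters
    ----------
    case_pairs : (exposed, total)
        Number of case pairs with an affected relative, and total case pairs.
    comparator_pairs : (exposed, total)
        Same for comparator (index unaffected) pairs.
    assumed_K : float
        Assumed population prevalence of the disease, in (0, 1).
    mode : {"cases_census", "both_margins"}
        ``cases_census`` (default) fixes only the index margin at K and leaves
        the relative margin at its reweighted empirical value.
        ``both_margins`` instead builds the table with *both* margins equal to
        K and the observed odds ratio (a symmetric-margin variant).
    """
    a, n_case = float(case_pairs[0]), float(case_pairs[1])
    c, n_comp = float(comparator_pairs[0]), float(comparator_pairs[1])
    if not 0.0 < assumed_K < 1.0:
        raise ValueError(f"assumed_K must be in (0, 1), got {assumed_K}")
    if n_comp <= 0:
        raise ValueError("comparator pair count must be positive")
    if a > n_case or c > n_comp:
        raise ValueError("exposed counts cannot exceed totals")

    if mode == "cases_census":
        # n_case / (n_case + w * n_comp) = K  =>  w as below
        w = n_case * (1.0 - assumed_K) / (assumed_K * n_comp)
        return WeightedTable2x2(a=a, b=n_case - a, c=w * c, d=w * (n_comp - c))
    if mode == "both_margins":
        raw = WeightedTable2x2(a=a, b=n_case - a, c=c, d=n_comp - c)
        or_ = raw.odds_ratio
        p11 = _joint_from_or(assumed_K, assumed_K, or_)
        total = n_case + n_comp
        return WeightedTable2x2(
            a=p11 * total,
            b=(assumed_K - p11) * total,
            c=(assumed_K - p11) * total,
            d=(1.0 - 2.0 * assumed_K + p11) * total,
        )
    raise ValueError(f"unknown reweighting mode: {mode!r}")


def _joint_from_or(p_row: float, p_col: float, odds_ratio: float) -> float:
    """Joint probability P11 of a 2x2 with given margins and odds ratio."""
    if odds_ratio == 1.0:
        return p_row * p_col
    # p11 solves OR = p11*(1-p_row-p_col+p11) / ((p_row-p11)*(p_col-p11))
    s = p_row + p_col
    aa = odds_ratio - 1.0
    bb = -(odds_ratio * s + (1.0 - s))
    cc = odds_ratio * p_row * p_col
    disc = bb * bb - 4.0 * aa * cc
    p11 = (-bb - math.sqrt(disc)) / (2.0 * aa)
    lo, hi = max(0.0, s - 1.0), min(p_row, p_col)
    if not lo <= p11 <= hi:
        p11 = (-bb + math.sqrt(disc)) / (2.0 * aa)
    return p11


def solve_tetrachoric(
    table: WeightedTable2x2,
    relatedness: float = 0.5,
    assumed_K: float | None = None,
    n_effective: float | None = None,
    tol: float = 1e-10,
) -> TetrachoricFit:
    """Solve the bivariate-normal threshold model for the latent correlation.

    Thresholds are the upper-tail normal quantiles of the two margins; ``rho``
    is found by bracketed root search so that the model's joint upper-tail
    probability matches the observed joint cell.  The objective is strictly
    increasing in ``rho``, so the bracket is guaranteed.

    The standard error of ``rho`` uses the delta method on the joint cell with
    thresholds treated as fixed: ``se = sqrt(p11 (1 - p11) / N) / phi2`` with
    ``phi2`` the bivariate normal density at the thresholds and ``N`` the
    total mass of the table being solved (the convention of latent-correlation
    software fed a weighted table).  The resulting interval ignores dependence
    between pairs from the same family, margin estimation error and the fact
    that reweighting inflates the nominal mass, so it can be anti-conservative;
    pass ``n_effective`` explicitly (e.g. the raw pre-reweighting pair count)
    for a more cautious interval.
    """
    total = table.total
    if total <= 0:
        raise ValueError("empty table")
    p_row = table.row1_margin
    p_col = table.col1_margin
    if not (0.0 < p_row < 1.0 and 0.0 < p_col < 1.0):
        raise ValueError(f"margins must be interior, got {p_row}, {p_col}")
    p11 = table.a / total
    t1 = stats.norm.isf(p_row)
    t2 = stats.norm.isf(p_col)
    n_eff = float(n_effective) if n_effective is not None else total

    or_ = table.odds_ratio
    if or_ == 1.0:
        rho = 0.0
    else:
        lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
        f = lambda r: bivariate_normal_upper_tail(t1, t2, r) - p11
        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            raise ValueError(
                "tetrachoric root not bracketable for table "
                f"a={table.a}, b={table.b}, c={table.c}, d={table.d} "
                f"(margins {p_row:.3g}/{p_col:.3g}, joint {p11:.3g})"
            )
        rho = optimize.brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)

    se = math.sqrt(p11 * (1.0 - p11) / n_eff) / _bvn_density(t1, t2, rho)
    return TetrachoricFit(
        rho=rho,
        t_index=t1,
        t_relative=t2,
        se_rho=se,
        relatedness=relatedness,
        assumed_K=assumed_K,
        n_effective=n_eff,
    )


class TetrachoricHeritability(BaseEstimator):
    """Narrow-sense heritability estimator for a dichotomous trait.

    Fits the liability-threshold model to a pair-level 2x2 affection table,
    optionally after reweighting an ascertained case/comparator sample back to
    the population, and reports ``h2 = rho / relatedness``.

    Parameters
    ----------
    assumed_prevalence : float, optional
        Population prevalence K used for the ascertainment correction.
        Required when ``reweight`` is not ``None``.
    relatedness : float, default 0.5
        Expected shared fraction of additive genetic variance for the pair
        kinship (0.5 for parent/offspring and full siblings).
    reweight : {"cases_census", "both_margins", None}, default "cases_census"
        Ascertainment correction mode; ``None`` treats the input table as
        already population-representative.
    effective_n : {"table", "raw"} or float, default "table"
        Sample size for the delta-method standard error: ``"table"`` uses the
        mass of the (possibly reweighted) table, ``"raw"`` the observed pair
        count before reweighting; a float is used verbatim.
    ci_level : float, default 0.95
        Nominal level of the Wald interval (reported on the h2 scale).

    Attributes
    ----------
    table_ : WeightedTable2x2
        The (reweighted) table the model was solved on.
    rho_, se_rho_ : float
        Tetrachoric correlation and its delta-method standard error.
    h2_ : float
        Estimated heritability; may fall outside [0, 1] by sampling noise, in
        which case a warning is emitted but the value is *not* truncated.
    ci_ : (float, float)
        Wald interval for h2.
    result_ : TetrachoricFit
        Full fit record including thresholds and provenance.

    Examples
    --------
    >>> est = TetrachoricHeritability(assumed_prevalence=1.4e-4)
    >>> est.fit([[13, 7602], [16, 37293]])  # doctest: +ELLIPSIS
    TetrachoricHeritability(...)
    >>> round(est.h2_ * 100)
    22
    """

    def __init__(
        self,
        assumed_prevalence: float | None = None,
        relatedness: float = 0.5,
        reweight: str | None = "cases_census",
        effective_n: str | float = "table",
        ci_level: float = 0.95,
    ):
        self.assumed_prevalence = assumed_prevalence
        self.relatedness = relatedness
        self.reweight = reweight
        self.effective_n = effective_n
        self.ci_level = ci_level

    def fit(self, X, y=None):
        """Fit the threshold model.

        Parameters
        ----------
        X : WeightedTable2x2 or array-like of shape (2, 2)
            ``[[a, b], [c, d]]`` with row 0 the case (index affected) pairs
            and row 1 the comparator pairs; columns are relative affected /
            unaffected.  When ``reweight`` is ``None`` the table is used as
            is; otherwise rows are case/comparator counts to be corrected.
        y : ignored
        """
        import warnings

        if isinstance(X, WeightedTable2x2):
            table = X
            self.n_raw_ = table.total
        else:
            arr = np.asarray(X, dtype=float)
            if arr.shape != (2, 2):
                raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
            if self.reweight is not None:
                if self.assumed_prevalence is None:
                    raise ValueError(
                        "assumed_prevalence is required when reweighting"
                    )
                table = reweight_to_population(
                    case_pairs=(arr[0, 0], arr[0].sum()),
                    comparator_pairs=(arr[1, 0], arr[1].sum()),
                    assumed_K=self.assumed_prevalence,
                    mode=self.reweight,
                )
                self.n_raw_ = float(arr.sum())
            else:
                table = WeightedTable2x2(
                    a=arr[0, 0], b=arr[0, 1], c=arr[1, 0], d=arr[1, 1]
                )
                self.n_raw_ = table.total

        if self.effective_n == "table":
            n_eff = table.total
        elif self.effective_n == "raw":
            n_eff = self.n_raw_
        else:
            n_eff = float(self.effective_n)
        fit = solve_tetrachoric(
            table,
            relatedness=self.relatedness,
            assumed_K=self.assumed_prevalence,
            n_effective=n_eff,
        )
        if self.ci_level != 0.95:
            z = stats.norm.isf((1.0 - self.ci_level) / 2.0)
            half = z * fit.se_rho
            fit.ci = (
                (fit.rho - half) / fit.relatedness,
                (fit.rho + half) / fit.relatedness,
            )
        self.table_ = table
        self.result_ = fit
        self.rho_ = fit.rho
        self.se_rho_ = fit.se_rho
        self.h2_ = fit.h2
        self.ci_ = fit.ci
        if not 0.0 <= self.h2_ <= 1.0:
            warnings.warn(
                f"h2 estimate {self.h2_:.3f} outside [0, 1]; reported "
                "untruncated (sampling noise can push the estimator out of "
                "bounds)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self


def estimate_heritability(
    case_pairs: tuple[float, float],
    comparator_pairs: tuple[float, float],
    assumed_K: float,
    relatedness: float = 0.5,
    reweight: str = "cases_census",
) -> TetrachoricFit:
    """Reweight an ascertained pair sample and solve for heritability.

    Composition of :func:`reweight_to_population` and
    :func:`solve_tetrachoric`; the returned fit carries full provenance
    (thresholds, assumed prevalence, effective N).
    """
    est = TetrachoricHeritability(
        assumed_prevalence=assumed_K, relatedness=relatedness, reweight=reweight
    )
    a, n_case = case_pairs
    c, n_comp = comparator_pairs
    est.fit([[a, n_case - a], [c, n_comp - c]])
    return est.result_


def prevalence_sweep(
    case_pairs: tuple[float, float],
    comparator_pairs: tuple[float, float],
    k_min: float = 0.00004,
    k_max: float = 0.00024,
    step: float = 0.000002,
    relatedness: float = 0.5,
):
    """Heritability as a function of the assumed population prevalence.

    Re-runs the reweight-then-solve procedure on a fixed grid of assumed
    prevalences (defaults: 0.004% to 0.024% in steps of 0.0002%) and returns a
    DataFrame with columns ``K, rho, h2, ci_low, ci_high``.
    """
    import pandas as pd

    if step <= 0:
        raise ValueError("step must be positive")
    if not (0.0 < k_min < k_max < 1.0):
        raise ValueError("prevalence range must satisfy 0 < k_min < k_max < 1")
    n_points = int(round((k_max - k_min) / step)) + 1
    grid = k_min + step * np.arange(n_points)
    rows = []
    for K in grid:
        fit = estimate_heritability(
            case_pairs, comparator_pairs, assumed_K=float(K),
            relatedness=relatedness,
        )
        rows.append(
            {"K": float(K), "rho": fit.rho, "h2": fit.h2,
             "ci_low": fit.ci[0], "ci_high": fit.ci[1]}
        )
    return pd.DataFrame(rows)
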