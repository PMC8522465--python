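# Methods

## The liability-threshold model and its assumptions

Disease is modelled as the dichotomisation of a latent standard-normal
liability: person *i* is affected iff `L_i > t`, with `t = Φ⁻¹(1 − K)` set by
the population prevalence `K`. Liability decomposes as `L = A + E` with
`A ~ N(0, h²)` additive-genetic and `E ~ N(0, 1 − h²)` independent
environmental noise. Four assumptions are built in throughout: (1) normally
distributed liability with a single threshold; (2) no assortative mating
(founders' liabilities are independent); (3) all genetic variance is
additive (no dominance or epistasis); (4) relatives share nothing but genes —
no common-environment component. Under these, the liability correlation of a
relative pair is `r·h²` with relatedness `r` (0.5 for parents, full siblings
and offspring), so heritability is estimated as the pair liability
correlation divided by `r`. Assumption (4) makes the estimate an *upper*
bound for real data: any shared environment is absorbed into `h²`.

## Estimators

### Tetrachoric heritability

`TetrachoricHeritability` solves the bivariate-normal threshold model for a
2×2 pair table. Thresholds are upper-tail normal quantiles of the two
margins; the latent correlation ρ solves
`P(L1 > t1, L2 > t2; ρ) = p11` by Brent root search on (−1, 1) with
tolerance 1e-10 (the objective is strictly increasing in ρ, so the bracket
is guaranteed; an exactly unit odds ratio short-circuits to ρ = 0).

The joint upper-tail probability is computed with Genz's hybrid algorithm
(Gauss–Legendre quadrature on the arcsine transform for |ρ| < 0.925, an
asymptotic expansion plus quadrature beyond), accurate to ~1e-15 and tested
against adaptive 2-D quadrature to 1e-9.

**Ascertainment correction.** Case pairs are a census of the affected
population; comparator pairs are a matched subsample. The population table
is rebuilt by up-weighting all comparator rows by the single factor that
makes the index-affected margin equal the assumed prevalence `K`
(`reweight="cases_census"`, the default). Row-proportional scaling leaves
the observed odds ratio unchanged; the relative-affected margin takes its
reweighted empirical value rather than being forced to `K`. A symmetric
variant (`"both_margins"`) that sets both margins to `K` while preserving
the odds ratio is provided for comparison; it changes the estimates by well
under a percentage point at rare-disease margins.

**Standard errors.** Delta method on the joint cell with thresholds treated
as fixed: `se(ρ) = sqrt(p11(1 − p11)/N) / φ₂(t1, t2; ρ)`. By default `N` is
the mass of the (reweighted) table — the convention of latent-correlation
software handed a weighted table. This interval ignores the dependence
between pairs from the same family, margin-estimation error and the nominal
inflation of mass by reweighting, so it can be anti-conservative; the
estimator accepts `effective_n="raw"` (the observed pair count) or an
explicit float for more cautious intervals. Out-of-[0, 1] heritability
estimates are reported with a warning rather than silently truncated, since
the estimator can legitimately leave the parameter space by sampling noise.

**Rare-disease limit.** As `K → 0` at fixed odds ratio, the OR converges to
the relative recurrence risk λ and the estimate approaches the classical
recurrence-risk (Falconer-style) value; this is checked numerically at
K = 1e-5.

### Familial-aggregation odds ratios

*Family level*: exact conditional logistic regression for 1:m matched sets
with a binary "≥1 affected relative" exposure. The single-parameter
conditional likelihood (`exp(x_case β) / (n1 e^β + n0)` per set) is
maximised by Newton–Raphson; only sets with within-set exposure variation
contribute. If the exposed-case count reaches the boundary of its attainable
range the likelihood is monotone (complete separation): the fit is flagged
and the affected interval bound is infinite instead of raising. The solver
is validated against grid-search/Brent maximisation of the likelihood and
against statsmodels' `ConditionalLogit`.

*Pair level*: outcome = index is a case, exposure = relative affected, one
observation per (index, relative) pair. Conditioning on the matched design
is done either by the conditional likelihood stratified on matched sets
(default) or by entering matching factors as covariates; how to combine
set-conditioning with family-level clustering is genuinely underdetermined,
so both are exposed behind `variant=`. The variance is a sandwich aggregated
over family clusters. In the conditional variant per-set scores are
aggregated to the family of the set's case before forming the meat matrix
(pairs of the case's family dominate the within-set dependence); in the
covariate-adjusted variant the clustering is exact row-level
(statsmodels cluster-robust covariance). Continuous covariates such as birth
year are standardised internally so the conditional likelihood's
exponentials stay in range; birth year enters linearly. Rank-deficient
designs raise an error naming the collinear columns.

### Prevalence sweep

`prevalence_sweep` re-runs reweight-then-solve on a fixed grid of assumed
prevalences (default 0.004%–0.024% in 0.0002% steps, 101 points) and
returns the h² curve with CI band; the pipeline renders it as a plot.

## The synthetic register generator

`simulate_registry` emulates the three linked registers the design needs.

* **Pedigrees** — nuclear families: two founders plus a Poisson
  (`mean_offspring`, default 2.0) number of children; sexes Bernoulli(½);
  founder birth years uniform on `birth_year_range` (default 1920–1975) with
  the father within ±5 years of the mother; child birth years 20–40 years
  after the mother's. Death follows a banded annual hazard (0.001 to age 40,
  0.004 to 60, 0.015 to 80, 0.10 beyond); deaths past the registry horizon
  are recorded as missing. Regions are drawn per family (default 2
  categories — a coarse residential-area factor used only for matching).
  A small fraction of founders (2%) is foreign-born to exercise the
  inclusion cascade. No migration, twins or assortative mating.
* **Liabilities** — founders draw `A ~ N(0, h²)`; children get the
  mid-parent mean plus Mendelian segregation noise `N(0, h²/2)`, keeping the
  additive variance at h² in every generation and giving first-degree pairs
  a liability correlation of exactly h²/2; environment is independent
  `N(0, 1 − h²)` for everyone.
* **Visits** — affected persons receive a care sequence from a uniformly
  drawn onset age (16–80; ≤18 yields a juvenile-coded phenotype) until death
  or the horizon, coded 710D/710E (ICD-9) before the 1997 era switch and
  M33.x/G72.4 (ICD-10) after, from the five accepted specialist departments,
  with inpatient-only care before the 2001 outpatient register. The sequence
  guarantees qualification whenever the person is under care inside the
  case-definition windows, so ascertainment sensitivity is controlled
  explicitly by `subthreshold_fraction`: that fraction of affected persons
  instead receives a single record engineered to fail the index definition.
  Persons also carry background visits with unrelated codes, and at
  `mimic_rate` one muscular-dystrophy/metabolic-myopathy-coded visit.
  There is no published onset-age model for IIM; the uniform draw is a
  deliberate stand-in that exercises the calendar-era logic.

All randomness flows through `numpy.random.Generator` seeded from the
configuration; identical config + seed reproduces every table bit-exactly.

**What the generator does not emulate** — realistic demography and
migration, diagnostic miscoding beyond the explicit sub-threshold and mimic
channels, secular trends in incidence, shared household environment, and
registry coverage gaps. Passing parameter-recovery tests therefore show that
the estimators invert the generating model correctly, not that real
registers satisfy that model.

## Scales and numerical choices

Test and simulation scales are chosen so the statistical checks are sharp at
desk scale: the generator default prevalence for tests is 1–5% rather than
the rare-disease regime (at 0.014% stable family counts would need >10⁷
persons), while the rare-disease regime itself is exercised analytically
through the reweighting/threshold machinery on published aggregate counts.
Parameter recovery uses 100 000 simulated sibling pairs per replicate and
20 replicates per heritability value; coverage checks use 40 replicates of
3 000 matched sets. The mimic code list shipped
(G71.0–G71.3, G72.3, E74.0, E75.2; ICD-9 359.0/359.1/271.0) is a documented
reconstruction and fully configurable.

Degenerate inputs are handled explicitly: empty or non-interior-margin
tables, zero comparator counts and invalid prevalences raise named errors;
zero cells leave the crude OR undefined/flagged and are never
continuity-corrected (a correction would silently distort the tetrachoric
input); matched strata with no eligible comparators are retained with an
empty comparator list.

## Known limitations

* The heritability CI understates uncertainty by construction (dependence
  between pairs of one family is ignored); treat it as approximate.
* The case definition's positive predictive value cannot be validated here;
  the simulator's sub-threshold channel models sensitivity, not specificity.
* Only first-degree kinship is implemented; half-siblings are recognised
  (and excluded from full-sibling analyses) but not analysed separately.
* Subtype classification is code-based; with several qualifying codes the
  earliest main-diagnosis code wins, a deterministic but arbitrary
  tie-break.
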