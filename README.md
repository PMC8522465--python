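# famliab

Familial aggregation and liability-threshold heritability of rare diseases
from registry-style family data.

`famliab` is for epidemiologists and statistical geneticists who want to
estimate how strongly a rare dichotomous disease clusters in families — and
how much of its liability variance is additive-genetic — from linked
national-register data (a population register, a multi-generation register
with parental links, and a patient register of ICD-coded healthcare visits).
It was built around the family-based design used for idiopathic inflammatory
myopathies (IIMs) in Swedish registers, and ships a synthetic register
generator so every stage is testable without access to any microdata.

## The model

A person's disease liability is a latent standard-normal variable
`L = A + E`, with additive genetic component `A ~ N(0, h²)` and independent
environment `E ~ N(0, 1 − h²)`; disease occurs when `L > t = Φ⁻¹(1 − K)`
for population prevalence `K`. For a pair of relatives sharing a fraction
`r` of additive variance (r = 0.5 for first-degree relatives), the two
liabilities are bivariate normal with correlation `ρ = r·h²`. The package
therefore estimates narrow-sense heritability as

```
h² = ρ̂ / r
```

where `ρ̂` is the tetrachoric correlation of the pair-level 2×2
affection-status table. Because cases enter as a census while comparators
are a matched subsample, the table is first reweighted so that its
index-affected margin equals the assumed population prevalence `K`
(comparator rows are scaled by a single factor, which leaves the observed
odds ratio untouched). Familial aggregation itself is summarised by odds
ratios: exact conditional logistic regression within 1:m matched sets at
the family level, and pair-level logistic models with a family-clustered
sandwich variance.

## Worked example

The bundled file `src/famliab/data/swedish_iim_pair_counts.csv` contains the
published aggregate pair counts of IIM among first-degree relatives of
Swedish register cases (1997–2016) and their matched comparators. The crude
odds-ratio table (counts below 5 suppressed):

```
$ famliab aggregate
         kinship  case_exposed  case_total  case_pct  comparator_exposed  comparator_total  comparator_pct  crude_or  suppressed
    ge1_relative            13        1620  0.802469                  16              7797        0.205207  3.934077       False
any_first_degree            13        7615  0.170716                  16             37309        0.042885  3.985867       False
          parent             2        2306  0.086730                   5             11414        0.043806       NaN        True
    full_sibling             9        2464  0.365260                  10             11685        0.085580  4.280041       False
       offspring             2        2845  0.070299                   1             14210        0.007037       NaN        True
```

0.80% of cases have ≥1 affected first-degree relative versus 0.21% of
comparators; the pair-level crude ORs are 3.99 (any first degree) and 4.28
(full siblings). Heritability at an assumed population prevalence of 0.014%:

```
$ famliab heritability
{
  "rho": 0.10885004628732602,
  "se_rho": 0.023988324966603934,
  "t_index": 3.6331335509472495,
  "t_relative": 3.3333530598986596,
  "relatedness": 0.5,
  "assumed_K": 0.00014,
  "h2": 0.21770009257465203,
  "ci_low": 0.12366585870556461,
  "ci_high": 0.31173432644373944
}
```

i.e. h² = 22% (95% CI 12–31%) among any first-degree relatives; the same
command with `--kinship full_sibling` gives 24% (12–37%). A prevalence
sensitivity sweep (`famliab sweep`, grid 0.004%–0.024% in 0.0002% steps,
101 points) moves the any-first-degree estimate only between 20.1% and
22.6%.

The same estimators are available as a library, sklearn-style:

```python
from famliab import TetrachoricHeritability
est = TetrachoricHeritability(assumed_prevalence=1.4e-4).fit(
    [[13, 7602], [16, 37293]]
)
est.h2_, est.ci_   # (0.2177..., (0.1237..., 0.3117...))
```

and the full simulate → ascertain → match → pair → estimate pipeline runs
with `famliab run --config run.yaml` (or `famliab.run_pipeline`), writing
attrition, descriptive, odds-ratio and heritability artefacts plus a seeded
run manifest.

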