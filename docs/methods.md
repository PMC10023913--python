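# Methods

`aircausal` implements a causal-inference pipeline for daily environmental
time series and daily pediatric asthma visit counts: lagged Spearman
screening, DAG-based backdoor identification, Poisson outcome modelling with
IQR-scaled effects, a three-probe refutation suite, and attributable-burden
arithmetic. This note records the models, the defaults and the reasoning
behind every choice that was genuinely open.

## The estimand and the outcome model

For an environmental variable $X_j$ and daily visit count $Y_t$, the
pipeline targets the effect of $X_{j,t-k}$ (exposure $k$ days before the
outcome, $k = 0..6$) on $E[Y_t]$, adjusted for the confounders implied by a
causal DAG. Lag $k$ always pairs outcome day $t$ with exposure day $t-k$ —
the standard epidemiologic convention in which exposure precedes outcome.
Rows are never paired across a calendar gap: alignment splits the series
into contiguous segments and aligns each independently.

The outcome model is a Poisson regression of $Y_t$ on the treatment(s) plus
the backdoor adjustment set. Two links are exposed:

* **identity** (default): $\lambda_t = \beta_0 + \sum_j \beta_j x_{jt}$.
  A coefficient is directly the per-unit effect in expected visits/day, and
  a joint one-unit increase of several treatments changes the rate by the
  sum of their coefficients. The default is the identity link because the
  effect scale throughout the package (and in the study design it follows)
  is additive counts-per-unit, and the pooled effect of a joint model is
  observed to match the coordinate sum — a signature of additivity.
* **log**: $\log \lambda_t = \eta_t$. Per-unit effects are then reported as
  the average marginal effect on the count scale,
  $\frac1n \sum_t [\hat\lambda(x_t + e_j) - \hat\lambda(x_t)]$, and the
  pooled effect is the joint finite difference (not the coordinate sum).

The "causal effect" scale is the per-unit effect multiplied by the
treatment's interquartile range (per-IQR effect): the change in expected
daily visits when the treatment rises by one IQR, which makes variables with
different units comparable. The IQR is computed once per variable on the
full series and reused at every lag, so a variable has a single IQR across
its lag profile.

Numerics: the GLM is fitted by IRLS (statsmodels) to relative tolerance
1e-8 with at most 100 iterations; non-convergence raises an error carrying
the iteration trace, never a silent result. Under the identity link the
iterations start from the ordinary-least-squares solution, which for count
data at these rates keeps the working means positive. Perfect collinearity
is detected by a rank check and reported with the offending column names;
an underdetermined fit (rows ≤ parameters) is rejected.

## Graphs and identification

A `CausalDAG` carries node roles (treatment / outcome / confounder /
unobserved) and directed edges. d-separation is decided by the ancestral
moral-graph construction (restrict to ancestors of the query, marry
co-parents, drop the conditioning set, test undirected reachability), which
implements the chain/fork/collider blocking rules including collider
unblocking by conditioned descendants. The test suite verifies exhaustive
agreement with a literal path-enumeration oracle on every DAG of up to five
nodes and every conditioning set, and spot-agreement with networkx's
d-separation on random larger graphs.

The adjustment set is canonical: the observed, non-treatment parents of the
treatments. It is returned only after verification — no member may descend
from a treatment, and in the graph with treatment-outgoing edges removed
each treatment must be d-separated from the outcome given the set plus the
remaining treatments. A minimal-set search was deliberately avoided: the
parent set is deterministic, always valid when any valid set exists in
these graph families, and cheap.

The default graphs encode the domain knowledge the analysis assumes. Four
meteorological confounders (humidity, temperature, sea-level pressure, wind
speed) drive every treatment and the outcome; precipitation (itself a
treatment) settles the pollutant treatments; the oxidant gases SO2/NO2/CO
feed fine particulate, PM2.5 feeds PM10, and the particulates feed the
composite index; every treatment points at the outcome (the unproven edges
under test). The exact arrow list inside the meteorology/pollutant block is
a package decision — the relationship families (settling, dispersion,
catalysis, interconversion) constrain but do not fix it — and is
serializable/overridable as an edge-list text format.

The unobserved-confounder node `U` points only at the outcome by default,
making the effects identified with the meteorological adjustment set. Where
`U` is allowed to point at treatments (`u_affects_treatments=True`), no
observed set blocks the backdoor paths and the pipeline reports
*not-identified* rather than estimating anyway. This assumption is
explicit and configurable precisely because it is the load-bearing one.

Two model families are built on a shared 14-node scaffold: a joint model
(8 treatments, 4 observed confounders, `U`, outcome) whose per-treatment
effects come from one joint fit, and single-treatment models in which the
other 7 candidate variables plus meteorology plus `U` are confounders (12
in total). The single models exist in a second variant without the four
meteorological nodes — removing the *indirect causes* that influence
treatments but are dropped from the outcome's direct parents — so the
influence of that adjustment can be compared across variants.

## Screening

Daily counts are heavily non-normal, so association screening uses the
Spearman rank correlation with average ranks for ties and a two-sided
p-value from the t approximation on n−2 degrees of freedom (appropriate at
n ≈ 2900; an exact permutation option exists for n ≤ 8 and is used as a
test oracle). No multiple-testing correction is applied across the
variable × lag grid; each cell is tested at α = 0.05 on its own. Two
selection rules are implemented: significance at *any* lag and at *all*
lags 0..6. The default is `all_lags`; `any_lag` is the permissive
alternative and both are exposed because reasonable screening practice
varies.

## Refutation

Three probes stress an estimate (defaults: 20 repetitions, subset fraction
0.8, relative tolerance 0.1 — all configurable and recorded in every
report, since no canonical values exist for them):

* **random common cause** — append an independent N(0,1) covariate to the
  adjustment set and re-estimate; pass when the mean relative change of the
  effect stays below the tolerance (absolute fallback when the original
  effect is numerically zero);
* **placebo treatment** — replace the treatment with an independent normal
  draw matched to its mean and SD (so scale-sensitive diagnostics remain
  comparable); pass when the mean placebo effect lies within two standard
  errors of zero (an absolute tolerance can be supplied instead);
* **data subset** — re-estimate on random subsets of the stated fraction;
  same relative-change rule. Fraction 1.0 reproduces the original exactly;
  a fraction too small to support the model is an error, not a pass.

An estimate is *robust* only when all three probes pass. All probes are
pure functions of (table, seed) and never mutate the caller's data.

## Attribution

A pollutant whose mean concentration fell from $C_a$ to $C_b$ over the
study period, with IQR $q$ and per-IQR causal effect $e$, is credited with

$$\text{attributable visits/year} = \frac{C_a - C_b}{q} \cdot e \cdot 365$$

and its share of the observed reduction is that quantity over the
difference in annual visit totals between the endpoint years. Choices:
`days_per_year = 365` (not 365.25 — the arithmetic is calendar-year
bookkeeping, not astronomy), and the per-IQR effect entering attribution is
the **maximum significant causal effect across lags** — the lag at which
the pollutant's causal influence peaks. A unit-coherence guard refuses a
concentration change whose unit tag differs from the unit recorded on the
environmental series; CO is the motivating case, being conventionally
reported in mg/m³ where the other gases use μg/m³.

## The synthetic data generator

Because the analysis needs data with known ground truth, the generator
produces:

* **meteorology** — annual-period sinusoid plus stationary AR(1) noise per
  variable (stationary initialization, so the first days are not atypical);
* **pollutants** — intercept + mean-centred linear couplings from
  meteorology and other pollutants + linear multi-year trend + AR(1) noise,
  truncated at zero (concentrations are non-negative; truncation, not
  reflection, for simplicity). Negative meteorological couplings produce
  the expected negative meteorology–pollutant and positive
  pollutant–pollutant correlations;
* **visits** — Poisson counts with rate
  $\lambda_t = \beta_0 + \sum_{(j,k)} \theta_{jk} X_{j,t-k}$ under the
  identity link (rate floored at a tiny ε) or $\exp(\eta_t)$ under the log
  link. Lag terms reaching before the series start are simply omitted for
  those first days;
* **cohort** — one record per visit; sex Bernoulli with configurable male
  share (default 0.6468), age from a piecewise-linear quantile function
  anchored at configurable quartiles (default 3/5/7 years) inside the
  pediatric range.

Defaults describe an eight-year (2922-day, 2014-01-01 start) record of a
subtropical-monsoon city: mean SO2 starting near 20 μg/m³ and trending to
≈ 5.8 (matching the published start/end means), NO2 declining by
≈ 12 μg/m³, CO from 0.89 to 0.65 mg/m³, with seasonal meteorology of
plausible magnitude. These level/trend anchors are taken from the published
summary figures; the sinusoid + AR(1) + linear-coupling form itself is the
simplest structure that reproduces the qualitative shape of such data and
supports every downstream test, and its remaining parameters (amplitudes,
AR coefficients, noise SDs, coupling coefficients) are package decisions,
not empirical facts. The default ground truth is a single effect of
**1.63 expected visits/day per μg/m³ of SO2 at lag 5** (1.63 × IQR 7 ≈ a
per-IQR effect of 11.4), with baseline rate 50/day, giving overall mean
counts near 70/day.

A single integer seed feeds a splittable generator (`SeedSequence`):
environment variables and the visit stream draw from independent child
streams, so every output is a pure function of (config, seed).

What the generator does **not** emulate: atmospheric chemistry, spatial
variation across monitoring stations (exposure is uniform by construction),
day-of-week or holiday visit patterns, overdispersion beyond Poisson,
pollen/behavioural covariates, and the epidemic-era collapse in visits.
Passing tests therefore demonstrate that the pipeline recovers effects when
its assumptions hold — not that those assumptions hold in any real city's
data.

## Problem sizes used by the test suite

The statistical checks run at the study scale where that is cheap and at
reduced scale elsewhere: parameter recovery and refuter calibration use 50
seeded replicates of the full 2922-day series; coverage and screening
properties use 600-day series over 20–30 seeds; the d-separation
equivalence check is exhaustive over all ≈1100 non-isomorphic DAGs of ≤ 5
nodes with every conditioning set (≈ 84,000 queries); type-I calibration
uses 1000 independent pairs of length 200. These sizes are the package's
own choices balancing statistical resolution against a fast test suite.

## Known limitations

* The identity-link Poisson model can in principle propose negative rates
  during fitting on adversarial data; the OLS warm start makes this rare
  but the fit will error rather than return nonsense.
* The canonical parent adjustment set is not minimal; with many observed
  parents it can be larger than necessary (harmless for bias, mildly
  costly for variance).
* Attribution is a point computation: no uncertainty interval is
  propagated from the effect estimate to the attributable burden.
* The refuter pass rules (relative tolerance 0.1, 2-SE placebo band) are
  conventions, not tests with controlled error rates; every report records
  the rule it applied.
* Seasonal confounding by shared annual cycles is adjusted only through
  the meteorological covariates; no explicit spline-of-time term is
  included.
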