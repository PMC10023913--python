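# aircausal

Causal inference for lagged air-quality effects on daily pediatric asthma
visits.

Association studies routinely link air pollutants and weather to asthma
exacerbations, but correlation alone cannot say whether cleaning the air
would reduce hospital visits. `aircausal` implements the full
causal-analysis chain for daily environmental time series paired with daily
visit counts, aimed at environmental epidemiologists and biostatisticians:

* **synthetic data** with known ground-truth effects — seasonal AR(1)
  meteorology, pollutants coupled to weather with declining multi-year
  trends, Poisson visit counts driven by lagged exposures — so every
  estimator can be checked for parameter recovery;
* **lagged Spearman screening** of each variable against visits at lags
  0–6 (exposure precedes outcome), with rule-based treatment selection;
* **causal DAGs** with d-separation and backdoor adjustment-set
  identification, including an explicit unobserved-confounder node `U`
  under which identification honestly fails;
* **Poisson outcome models** (identity or log link) giving per-unit
  effects, pooled multi-treatment effects, and per-IQR *causal effects*
  (effect × interquartile range) swept across lags;
* **refutation probes** — random common cause, placebo treatment, data
  subset — with a joint robustness verdict;
* **attributable burden**: converting a pollutant's multi-year
  concentration decline into attributable annual visits,
  `((C_start − C_end)/IQR) × per-IQR effect × 365`, and its share of the
  observed reduction.

The core estimand, for treatment $X_j$ at lag $k$ with backdoor adjustment
set $Z$: the change in expected daily visits $E[Y_t]$ per unit (and per
IQR) increase of $X_{j,t-k}$, from the Poisson regression
$Y_t \sim \text{Poisson}(\beta_0 + \beta_j X_{j,t-k} + \gamma' Z_{t-k})$.

## Worked example

Attribution from published inputs (`examples/attribute_reduction.py`):

```text
observed reduction in annual visits: 16845
SO2 (20.08 -> 5.83 μg/m³, IQR 7, effect 11.41):  8478.04 visits/year
NO2 (Δ 12.25 μg/m³, IQR 23, effect 6.90):        1341.38 visits/year
SO2 share of the observed reduction: 50.3%
```

Reading: an SO2 decline of 14.25 μg/m³ is 2.04 IQRs; at 11.41 fewer
expected visits/day per IQR that is ≈ 23.2 visits/day, or ≈ 8478 visits per
year — about half of the observed fall in annual visits between the first
and last study years.

Parameter recovery on synthetic data (`examples/estimate_effects.py`; the
generator's ground truth is 1.63 visits/day per μg/m³ of SO2 at lag 5):

```text
adjustment set: ['humidity', 'precipitation', 'sea_level_pressure', 'temperature', 'wind_speed']
lag  per-unit  per-IQR         p
  0     0.930     7.09 2.31e-217
  ...
  5     1.625    12.39  0.00e+00
  6     1.290     9.83  0.00e+00
```

The estimate at the true lag recovers 1.63 to within sampling error; the
neighbouring lags show attenuated echoes because day-to-day SO2 is
autocorrelated. The other scripts in `examples/` walk through simulation,
screening, refutation and the end-to-end pipeline; each prints what it
computes and what the numbers mean.

A thin CLI wraps the pipeline for shell use:

```bash
aircausal run --seed 1 --out results/
aircausal attribute 20.08 5.83 7 11.41
```

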