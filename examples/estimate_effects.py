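"""Backdoor-adjusted Poisson estimation of a single treatment across lags.

The single-treatment DAG names SO2 the treatment; the backdoor criterion
yields its observed parents (precipitation + four meteorological
confounders) as the adjustment set.  An identity-link Poisson regression at
each lag gives the per-unit effect (visits/day per μg/m³), which times the
IQR gives the per-IQR "causal effect".
"""
from aircausal import (
    backdoor_set,
    build_single_treatment_dag,
    default_config,
    run_lag_sweep,
    simulate,
)

env, visits = simulate(default_config(seed=1))
dag = build_single_treatment_dag("so2", include_indirect=True)
print("adjustment set:", sorted(backdoor_set(dag)))

sweep = run_lag_sweep(env, visits, dag, lags=range(7), alpha=0.05)
print(f"{'lag':>3} {'per-unit':>9} {'per-IQR':>8} {'p':>9}")
for _, row in sweep.iterrows():
    print(
        f"{int(row['lag']):>3} {row['per_unit_effect']:>9.3f} "
        f"{row['causal_effect']:>8.2f} {row['p_value']:>9.2e}"
    )
# The per-unit estimate at lag 5 recovers the generator's ground truth
# (1.63 visits/day per μg/m³); other lags show attenuated echoes because
# SO2 on neighbouring days is correlated with the truly causal day.
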