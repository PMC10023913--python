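"""Poisson outcome models: recovery, marginal effects, IQR scaling, lag sweeps."""
import numpy as np
import pandas as pd
import pytest

from aircausal import (
    backdoor_set,
    build_multiple_treatment_dag,
    build_single_treatment_dag,
    default_config,
    fit_outcome_model,
    lag_align,
    marginal_effect,
    pooled_effect,
    run_lag_sweep,
    scale_by_iqr,
    simulate,
    sweep_to_wide,
)
from aircausal.estimation import EstimationError


def _small_table(n=300, seed=0, link="identity", beta=(20.0, 1.5, -0.8)):
    """Hand-built Poisson data with known coefficients."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 10, n)
    x2 = rng.uniform(0, 5, n)
    b0, b1, b2 = beta
    eta = b0 + b1 * x1 + b2 * x2
    lam = np.exp(eta) if link == "log" else np.maximum(eta, 1e-8)
    y = rng.poisson(lam)
    return pd.DataFrame({"visits": y, "x1": x1, "x2": x2})


class TestFitOutcomeModel:
    def test_null_effect_coefficients_cover_zero(self):
        """With visits independent of all treatments the Wald interval
        estimate ± 2 SE covers zero at close to its nominal rate."""
        hits = total = 0
        for seed in range(30):
            cfg = default_config(n_days=600, seed=seed, true_effects={})
            env, visits = simulate(cfg)
            dag = build_multiple_treatment_dag()
            table = lag_align(env, visits, 1)
            model = fit_outcome_model(table, dag.treatments, sorted(backdoor_set(dag)))
            for t in dag.treatments:
                est, se, _ = model.coefficient(t)
                hits += abs(est) < 2 * se
                total += 1
        assert hits / total >= 0.90

    def test_known_per_unit_effect_recovered_within_two_se(self):
        cfg = default_config(n_days=2922, seed=21, true_effects={("so2", 5): 1.59})
        env, visits = simulate(cfg)
        dag = build_single_treatment_dag("so2", True)
        table = lag_align(env, visits, 5)
        adj = sorted(backdoor_set(dag))
        model = fit_outcome_model(table, ["so2"], adj)
        est, se, p = model.coefficient("so2")
        assert abs(est - 1.59) < 2 * se
        assert p < 0.05

    def test_single_observation_rejected(self):
        table = pd.DataFrame({"visits": [3], "x1": [1.0]})
        with pytest.raises(EstimationError):
            fit_outcome_model(table, ["x1"])

    def test_collinear_columns_named(self):
        table = _small_table()
        table["x1_copy"] = table["x1"]
        with pytest.raises(EstimationError, match="x1"):
            fit_outcome_model(table, ["x1", "x1_copy"], ["x2"])

    def test_missing_columns_and_bad_outcome_rejected(self):
        table = _small_table()
        with pytest.raises(EstimationError, match="x9"):
            fit_outcome_model(table, ["x9"])
        bad = table.copy()
        bad["visits"] = bad["visits"] + 0.5
        with pytest.raises(EstimationError):
            fit_outcome_model(bad, ["x1"])


class TestMarginalEffects:
    def test_identity_link_effect_is_the_coefficient(self):
        table = _small_table(seed=3)
        model = fit_outcome_model(table, ["x1"], ["x2"], link="identity")
        assert marginal_effect(model, "x1") == model.result.params["x1"]

    def test_log_link_effect_matches_rowwise_finite_difference_oracle(self):
        table = _small_table(n=400, seed=5, link="log", beta=(1.0, 0.3, -0.1))
        model = fit_outcome_model(table, ["x1"], ["x2"], link="log")
        params = model.result.params
        lam = np.exp(
            params["const"] + params["x1"] * table["x1"] + params["x2"] * table["x2"]
        )
        lam_shift = np.exp(
            params["const"] + params["x1"] * (table["x1"] + 1) + params["x2"] * table["x2"]
        )
        oracle = float(np.mean(lam_shift - lam))
        assert marginal_effect(model, "x1") == pytest.approx(oracle, rel=1e-10)

    def test_null_log_model_has_near_zero_effect(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {"visits": rng.poisson(75, 400), "x1": rng.normal(size=400)}
        )
        model = fit_outcome_model(table, ["x1"], link="log")
        est, se, _ = model.coefficient("x1")
        assert abs(est) < 3 * se

    def test_unknown_treatment_rejected(self):
        model = fit_outcome_model(_small_table(), ["x1"], ["x2"])
        with pytest.raises(EstimationError):
            marginal_effect(model, "x2")


class TestPooledEffect:
    def test_identity_pooled_is_sum_of_coordinates(self):
        table = _small_table(seed=7)
        model = fit_outcome_model(table, ["x1", "x2"])
        total = pooled_effect(model)
        assert total == pytest.approx(
            model.result.params["x1"] + model.result.params["x2"], abs=1e-12
        )

    def test_printed_joint_model_is_internally_additive(self):
        """The reported per-treatment lag-1 effects must sum to the reported
        pooled lag-1 effect up to two-decimal rounding of nine numbers."""
        per_treatment = [0.04, 0.10, 0.02, -0.14, -0.05, 0.93, 0.11, 0.02]
        pooled = 1.02
        assert abs(sum(per_treatment) - pooled) <= 0.045

    def test_log_pooled_matches_joint_shift_oracle(self):
        table = _small_table(n=400, seed=8, link="log", beta=(1.0, 0.2, 0.15))
        model = fit_outcome_model(table, ["x1", "x2"], link="log")
        params = model.result.params

        def lam(s1, s2):
            return np.exp(
                params["const"]
                + params["x1"] * (table["x1"] + s1)
                + params["x2"] * (table["x2"] + s2)
            )

        oracle = float(np.mean(lam(1, 1) - lam(0, 0)))
        assert pooled_effect(model) == pytest.approx(oracle, rel=1e-10)
        # multiplicative model: joint shift is not the sum of coordinates
        coords = marginal_effect(model, "x1") + marginal_effect(model, "x2")
        assert pooled_effect(model) != pytest.approx(coords, rel=1e-6)

    def test_empty_treatment_list_rejected(self):
        model = fit_outcome_model(_small_table(), ["x1"])
        with pytest.raises(EstimationError):
            pooled_effect(model, [])


class TestIqrScaling:
    def test_per_unit_times_iqr(self):
        assert scale_by_iqr(1.59, 7.0) == pytest.approx(11.13, abs=1e-9)

    def test_zero_iqr_and_sign_preservation(self):
        assert scale_by_iqr(123.4, 0.0) == 0.0
        assert scale_by_iqr(-2.0, 3.0) < 0

    def test_negative_iqr_rejected(self):
        with pytest.raises(EstimationError):
            scale_by_iqr(1.0, -1.0)


class TestLagSweep:
    def test_single_lag_gives_one_row_per_treatment(self, small_sim):
        _, env, visits = small_sim
        dag = build_multiple_treatment_dag()
        sweep = run_lag_sweep(env, visits, dag, lags=[0])
        # 8 treatments + 1 pooled row
        assert len(sweep) == 9
        assert set(sweep["lag"]) == {0}

    def test_causal_effect_identity_holds_exactly(self, small_sim):
        _, env, visits = small_sim
        dag = build_single_treatment_dag("so2", True)
        sweep = run_lag_sweep(env, visits, dag, lags=range(3))
        finite = sweep[np.isfinite(sweep["iqr"])]
        np.testing.assert_array_equal(
            finite["causal_effect"].to_numpy(),
            (finite["per_unit_effect"] * finite["iqr"]).to_numpy(),
        )

    def test_not_identified_rows_carry_no_estimates(self, small_sim):
        _, env, visits = small_sim
        dag = build_single_treatment_dag("so2", True, u_affects_treatments=True)
        sweep = run_lag_sweep(env, visits, dag, lags=[0, 1])
        assert (~sweep["identified"]).all()
        assert sweep["per_unit_effect"].isna().all()
        assert not sweep["significant"].any()

    def test_excluding_indirect_causes_shifts_estimates(self, small_sim):
        """Dropping the meteorological adjustment changes the estimate when
        part of the association is routed through meteorology."""
        _, env, visits = small_sim
        with_met = run_lag_sweep(
            env, visits, build_single_treatment_dag("so2", True), lags=[5]
        )
        without_met = run_lag_sweep(
            env, visits, build_single_treatment_dag("so2", False), lags=[5]
        )
        a = float(with_met["per_unit_effect"].iloc[0])
        b = float(without_met["per_unit_effect"].iloc[0])
        assert a != pytest.approx(b, rel=1e-6)

    def test_wide_table_shape(self, small_sim):
        _, env, visits = small_sim
        dag = build_multiple_treatment_dag()
        wide = sweep_to_wide(run_lag_sweep(env, visits, dag, lags=range(7)))
        assert {f"lag{k}" for k in range(7)} <= set(wide.columns)
        assert len(wide) == 9
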