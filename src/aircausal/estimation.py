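"""Backdoor-adjusted Poisson outcome models and IQR-scaled causal effects.

The outcome is a daily count, modelled by Poisson regression of visits on
the treatment(s) plus the backdoor adjustment set.  Two links are exposed:

* ``identity`` (default) — the rate is additive in the covariates, so a
  coefficient is directly the per-unit effect in expected visits/day and a
  joint one-unit increase of several treatments adds their coefficients;
* ``log`` — multiplicative rates; per-unit effects are reported as the
  average marginal effect on the count scale (mean finite difference of the
  fitted rate under a one-unit treatment increase).

A per-unit effect times the treatment's interquartile range gives the
"causal effect" scale used throughout: the change in expected daily visits
when the treatment rises by one IQR, which makes variables with different
units comparable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graphs import CausalDAG, backdoor_set
from .timeseries import EnvSeries, VisitSeries, compute_iqr, lag_align

__all__ = [
    "EstimationError",
    "ModelFitError",
    "EffectEstimate",
    "FittedOutcomeModel",
    "fit_outcome_model",
    "marginal_effect",
    "pooled_effect",
    "scale_by_iqr",
    "run_lag_sweep",
    "sweep_to_wide",
]


class EstimationError(ValueError):
    """Invalid estimation input."""


class ModelFitError(RuntimeError):
    """The maximum-likelihood fit did not converge; carries the iteration trace."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history


@dataclass
class EffectEstimate:
    """One treatment × lag effect row.

    ``per_unit_effect`` is expected visits per unit exposure;
    ``causal_effect`` is exactly ``per_unit_effect * iqr`` (per-IQR scale).
    """

    treatment: str
    lag: int
    per_unit_effect: float
    standard_error: float
    p_value: float
    iqr: float
    causal_effect: float
    model_kind: str
    significant: bool
    identified: bool = True


@dataclass
class FittedOutcomeModel:
    """A fitted Poisson outcome model plus the design it was fitted on."""

    result: "sm.GLM"
    table: pd.DataFrame
    treatments: list[str]
    adjustment: list[str]
    link: str
    outcome: str

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def coefficient(self, name: str) -> tuple[float, float, float]:
        """(estimate, standard error, two-sided Wald p) for one column."""
        if name not in self.result.params.index:
            raise EstimationError(f"{name!r} is not a model term")
        return (
            float(self.result.params[name]),
            float(self.result.bse[name]),
            float(self.result.pvalues[name]),
        )


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    cols = list(X.columns)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank == len(cols):
        return []
    bad = []
    for c in cols:
        if c == "const":
            continue
        sub = X.drop(columns=[c] + bad)
        if np.linalg.matrix_rank(sub.to_numpy()) == rank - len(bad):
            bad.append(c)
            if np.linalg.matrix_rank(X.drop(columns=bad).to_numpy()) == len(cols) - len(bad):
                break
    return bad


def fit_outcome_model(
    table: pd.DataFrame,
    treatments: Sequence[str],
    adjustment: Sequence[str] = (),
    link: str = "identity",
    outcome: str = "visits",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FittedOutcomeModel:
    """Poisson regression of the outcome on treatments + adjustment set.

    Fitted by iteratively reweighted least squares to a relative tolerance of
    ``tol``; non-convergence raises :class:`ModelFitError` with the iteration
    trace rather than returning a silent result.  Under the identity link the
    IRLS iterations start from the least-squares solution, which keeps the
    working rates positive for count data of this kind.
    """
    treatments = list(treatments)
    adjustment = list(adjustment)
    if not treatments:
        raise EstimationError("at least one treatment is required")
    missing = [c for c in treatments + adjustment + [outcome] if c not in table.columns]
    if missing:
        raise EstimationError(f"table lacks columns {missing}")
    if link not in ("identity", "log"):
        raise EstimationError(f"unknown link {link!r}")
    y = table[outcome].to_numpy(dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise EstimationError("outcome must hold non-negative integer counts")
    X = sm.add_constant(table[treatments + adjustment].astype(float), has_constant="add")
    n, p = X.shape
    if n <= p:
        raise EstimationError(f"underdetermined model: {n} rows for {p} parameters")
    bad = _find_collinear(X)
    if bad:
        raise EstimationError(f"perfectly collinear columns: {bad}")

    import warnings

    from statsmodels.tools.sm_exceptions import DomainWarning

    if link == "identity":
        family = sm.families.Poisson(link=sm.families.links.Identity())
        start, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    else:
        family = sm.families.Poisson()
        start = None
    with warnings.catch_warnings():
        # identity-link Poisson is the intended additive-rate model;
        # statsmodels warns that the link leaves the canonical domain
        warnings.simplefilter("ignore", DomainWarning)
        model = sm.GLM(y, X, family=family)
    result = model.fit(start_params=start, maxiter=maxiter, tol=tol)
    if not getattr(result, "converged", True):
        raise ModelFitError(
            f"IRLS did not converge within {maxiter} iterations",
            history=getattr(result, "fit_history", None),
        )
    return FittedOutcomeModel(
        result=result,
        table=table,
        treatments=treatments,
        adjustment=adjustment,
        link=link,
        outcome=outcome,
    )


def _rate(model: FittedOutcomeModel, X: pd.DataFrame) -> np.ndarray:
    eta = X.to_numpy() @ model.result.params.to_numpy()
    return np.exp(eta) if model.link == "log" else eta


def marginal_effect(model: FittedOutcomeModel, treatment: str) -> float:
    """Per-unit effect of one treatment on the expected daily count.

    Identity link: the coefficient itself.  Log link: the average over
    observed rows of λ̂(x with treatment + 1) − λ̂(x).
    """
    if treatment not in model.treatments:
        raise EstimationError(f"{treatment!r} is not a treatment in this model")
    if model.link == "identity":
        return float(model.result.params[treatment])
    X = sm.add_constant(
        model.table[model.treatments + model.adjustment].astype(float), has_constant="add"
    )
    shifted = X.copy()
    shifted[treatment] = shifted[treatment] + 1.0
    return float(np.mean(_rate(model, shifted) - _rate(model, X)))


def pooled_effect(model: FittedOutcomeModel, treatments: Sequence[str] | None = None) -> float:
    """Average marginal effect of raising all treatments by one unit at once.

    Under the identity link this equals the sum of the coordinate effects
    exactly; under the log link it is the joint finite difference, which in
    general differs from the sum.
    """
    ts = list(treatments) if treatments is not None else list(model.treatments)
    if not ts:
        raise EstimationError("pooled_effect requires a nonempty treatment list")
    for t in ts:
        if t not in model.treatments:
            raise EstimationError(f"{t!r} is not a treatment in this model")
    if model.link == "identity":
        return float(sum(model.result.params[t] for t in ts))
    X = sm.add_constant(
        model.table[model.treatments + model.adjustment].astype(float), has_constant="add"
    )
    shifted = X.copy()
    for t in ts:
        shifted[t] = shifted[t] + 1.0
    return float(np.mean(_rate(model, shifted) - _rate(model, X)))


def _pooled_wald(model: FittedOutcomeModel, ts: Sequence[str]) -> tuple[float, float]:
    """Standard error and two-sided p for the sum of coefficients (identity)."""
    from scipy import stats

    cov = model.result.cov_params()
    idx = list(ts)
    var = float(cov.loc[idx, idx].to_numpy().sum())
    se = float(np.sqrt(var))
    est = float(sum(model.result.params[t] for t in ts))
    z = est / se if se > 0 else np.inf
    return se, float(2 * stats.norm.sf(abs(z)))


def scale_by_iqr(per_unit: float, iqr: float) -> float:
    """Per-IQR ("causal") effect: per-unit effect × interquartile range."""
    if iqr < 0:
        raise EstimationError("iqr must be non-negative")
    return float(per_unit) * float(iqr)


def run_lag_sweep(
    env: EnvSeries,
    visits: VisitSeries,
    dag: CausalDAG,
    lags: Iterable[int] = range(7),
    alpha: float = 0.05,
    link: str = "identity",
) -> pd.DataFrame:
    """Fit the DAG-implied outcome model at each lag; one row per treatment × lag.

    The adjustment set comes from the backdoor criterion on ``dag``.  If the
    effect is not identified (an unobserved confounder points into a
    treatment), rows are emitted with ``identified=False`` and no fabricated
    estimates.  Treatment IQRs are computed once on the full lag-0 series and
    reused at every lag.  For the multiple-treatment model a ``pooled`` row
    per lag reports the joint one-unit effect (its IQR column is NaN — no
    single spread applies to a joint shift).
    """
    treatments = dag.treatments
    if not treatments:
        raise EstimationError("DAG declares no treatment nodes")
    adj = backdoor_set(dag)
    iqrs = {t: compute_iqr(env.data[t].to_numpy()) for t in treatments}
    rows: list[EffectEstimate] = []
    for lag in sorted(set(int(k) for k in lags)):
        if adj is None:
            for t in treatments:
                rows.append(
                    EffectEstimate(
                        treatment=t,
                        lag=lag,
                        per_unit_effect=float("nan"),
                        standard_error=float("nan"),
                        p_value=float("nan"),
                        iqr=iqrs[t],
                        causal_effect=float("nan"),
                        model_kind=dag.kind,
                        significant=False,
                        identified=False,
                    )
                )
            continue
        table = lag_align(env, visits, lag)
        model = fit_outcome_model(
            table, treatments=treatments, adjustment=sorted(adj), link=link
        )
        for t in treatments:
            per_unit = marginal_effect(model, t)
            _, se, p = model.coefficient(t)
            rows.append(
                EffectEstimate(
                    treatment=t,
                    lag=lag,
                    per_unit_effect=per_unit,
                    standard_error=se,
                    p_value=p,
                    iqr=iqrs[t],
                    causal_effect=scale_by_iqr(per_unit, iqrs[t]),
                    model_kind=dag.kind,
                    significant=bool(p < alpha),
                )
            )
        if dag.kind == "multiple":
            pooled = pooled_effect(model, treatments)
            if link == "identity":
                se, p = _pooled_wald(model, treatments)
            else:
                se, p = float("nan"), float("nan")
            rows.append(
                EffectEstimate(
                    treatment="pooled",
                    lag=lag,
                    per_unit_effect=pooled,
                    standard_error=se,
                    p_value=p,
                    iqr=float("nan"),
                    causal_effect=float("nan"),
                    model_kind=dag.kind,
                    significant=bool(p < alpha) if np.isfinite(p) else False,
                )
            )
    frame = pd.DataFrame([vars(r) for r in rows])
    return frame.sort_values(["treatment", "lag"], kind="stable").reset_index(drop=True)


def sweep_to_wide(sweep: pd.DataFrame) -> pd.DataFrame:
    """Reshape a lag-sweep table to one row per treatment with lag columns.

    Columns: treatment, iqr, ``lag{k}`` per-IQR causal effect (per-unit for
    the pooled row), ``sig_lag{k}`` significance flags.
    """
    out_rows = []
    for t, grp in sweep.groupby("treatment", sort=False):
        row: dict = {"treatment": t, "iqr": grp["iqr"].iloc[0]}
        for _, r in grp.sort_values("lag").iterrows():
            value = r["causal_effect"] if np.isfinite(r["iqr"]) else r["per_unit_effect"]
            row[f"lag{int(r['lag'])}"] = value
            row[f"sig_lag{int(r['lag'])}"] = bool(r["significant"])
        out_rows.append(row)
    return pd.DataFrame(out_rows)
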