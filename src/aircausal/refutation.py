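"""Refutation probes: random common cause, placebo treatment, data subset.

A point estimate is only as credible as the assumptions behind it, so every
estimate is stress-tested three ways:

* random common cause — append an independent standard-normal covariate to
  the adjustment set and re-estimate; a well-specified estimate should not
  move (pass when the mean relative change stays below a tolerance);
* placebo treatment — replace the treatment column with an independent
  random draw matched to its mean and spread; the re-estimated effect should
  vanish (pass when the mean placebo effect is within two standard errors of
  zero, or an absolute tolerance if configured);
* data subset — re-estimate on random row subsets; a stable estimate changes
  little (same relative-change rule as the common-cause probe).

An estimate is labelled robust only when all three probes pass.  All probes
are pure functions of (table, seed): the caller's data is never mutated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import EstimationError, fit_outcome_model, marginal_effect

__all__ = [
    "RefutationError",
    "RefutationReport",
    "refute_random_common_cause",
    "refute_placebo",
    "refute_subset",
    "is_robust",
]

_EPS = 1e-9


class RefutationError(ValueError):
    """Invalid refutation request."""


@dataclass
class RefutationReport:
    """Outcome of one refutation probe."""

    method: str
    original_effect: float
    refuted_effects: np.ndarray
    repetitions: int
    tolerance: float
    passed: bool
    seed: int

    def summary(self) -> dict:
        return {
            "method": self.method,
            "original_effect": self.original_effect,
            "mean_refuted_effect": float(np.mean(self.refuted_effects)),
            "repetitions": self.repetitions,
            "tolerance": self.tolerance,
            "passed": self.passed,
            "seed": self.seed,
        }


def _original(table, treatment, adjustment, link, outcome):
    model = fit_outcome_model(table, [treatment], adjustment, link=link, outcome=outcome)
    return marginal_effect(model, treatment)


def _relative_pass(original: float, refuted: np.ndarray, tolerance: float) -> bool:
    scale = max(abs(original), _EPS)
    if abs(original) <= _EPS:
        # degenerate original: fall back to an absolute criterion
        return bool(np.mean(np.abs(refuted - original)) < tolerance)
    return bool(np.mean(np.abs(refuted - original)) / scale < tolerance)


def refute_random_common_cause(
    table: pd.DataFrame,
    treatment: str,
    adjustment: list[str],
    link: str = "identity",
    outcome: str = "visits",
    reps: int = 20,
    seed: int = 0,
    tolerance: float = 0.1,
) -> RefutationReport:
    """Re-estimate with an extra independent N(0,1) covariate, ``reps`` times."""
    if reps < 1:
        raise RefutationError("reps must be >= 1")
    original = _original(table, treatment, adjustment, link, outcome)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    refuted = np.empty(reps)
    for i in range(reps):
        aug = table.copy()
        aug["_random_common_cause"] = rng.normal(size=len(table))
        model = fit_outcome_model(
            aug, [treatment], adjustment + ["_random_common_cause"], link=link, outcome=outcome
        )
        refuted[i] = marginal_effect(model, treatment)
    return RefutationReport(
        method="random_common_cause",
        original_effect=original,
        refuted_effects=refuted,
        repetitions=reps,
        tolerance=tolerance,
        passed=_relative_pass(original, refuted, tolerance),
        seed=seed,
    )


def refute_placebo(
    table: pd.DataFrame,
    treatment: str,
    adjustment: list[str],
    link: str = "identity",
    outcome: str = "visits",
    reps: int = 20,
    seed: int = 0,
    tolerance: float | None = None,
) -> RefutationReport:
    """Replace the treatment with an independent draw matched to its marginal
    mean and SD; the effect should vanish.

    Pass rule: |mean refuted effect| < 2 × (mean refuted standard error), or
    |mean| < ``tolerance`` when an absolute tolerance is supplied.
    """
    if reps < 1:
        raise RefutationError("reps must be >= 1")
    x = table[treatment].to_numpy(dtype=float)
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0.0:
        raise RefutationError(f"treatment {treatment!r} has zero variance")
    original = _original(table, treatment, adjustment, link, outcome)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    refuted = np.empty(reps)
    ses = np.empty(reps)
    for i in range(reps):
        placebo = table.copy()
        placebo[treatment] = rng.normal(mu, sd, size=len(table))
        model = fit_outcome_model(placebo, [treatment], adjustment, link=link, outcome=outcome)
        refuted[i] = marginal_effect(model, treatment)
        _, ses[i], _ = model.coefficient(treatment)
    mean_effect = float(np.mean(refuted))
    if tolerance is None:
        passed = bool(abs(mean_effect) < 2.0 * float(np.mean(ses)))
        tol_recorded = 2.0 * float(np.mean(ses))
    else:
        passed = bool(abs(mean_effect) < tolerance)
        tol_recorded = tolerance
    return RefutationReport(
        method="placebo_treatment",
        original_effect=original,
        refuted_effects=refuted,
        repetitions=reps,
        tolerance=tol_recorded,
        passed=passed,
        seed=seed,
    )


def refute_subset(
    table: pd.DataFrame,
    treatment: str,
    adjustment: list[str],
    fraction: float = 0.8,
    link: str = "identity",
    outcome: str = "visits",
    reps: int = 20,
    seed: int = 0,
    tolerance: float = 0.1,
) -> RefutationReport:
    """Re-estimate on random row subsets of the stated fraction."""
    if reps < 1:
        raise RefutationError("reps must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise RefutationError("fraction must lie in (0, 1]")
    n = len(table)
    m = int(round(fraction * n))
    p = len(adjustment) + 2
    if m <= p:
        raise RefutationError(
            f"subset of {m} rows cannot support a {p}-parameter model"
        )
    original = _original(table, treatment, adjustment, link, outcome)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    refuted = np.empty(reps)
    for i in range(reps):
        if fraction >= 1.0:
            sub = table
        else:
            idx = rng.choice(n, size=m, replace=False)
            sub = table.iloc[np.sort(idx)]
        model = fit_outcome_model(sub, [treatment], adjustment, link=link, outcome=outcome)
        refuted[i] = marginal_effect(model, treatment)
    return RefutationReport(
        method="data_subset",
        original_effect=original,
        refuted_effects=refuted,
        repetitions=reps,
        tolerance=tolerance,
        passed=_relative_pass(original, refuted, tolerance),
        seed=seed,
    )


def is_robust(reports: list[RefutationReport]) -> bool:
    """Robust iff every probe passed (all three methods expected)."""
    if not reports:
        raise RefutationError("no refutation reports supplied")
    return all(r.passed for r in reports)
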