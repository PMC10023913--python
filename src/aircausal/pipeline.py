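"""End-to-end pipeline orchestration, cohort summaries and report bundles.

``run_pipeline`` sequences the full analysis — simulate or load data,
deduplicate patient records, lag-screen, select treatments, build and
identify the causal graphs, sweep effects over lags, refute the leading
estimate, and attribute multi-year pollutant improvements — writing every
table as CSV plus a JSON manifest that records each stage, the parameters
and seeds it used, and SHA-256 hashes of the files it produced.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .attribution import AttributionError, attribute_pollutant, select_attribution_effect
from .estimation import run_lag_sweep, sweep_to_wide
from .graphs import backdoor_set, build_multiple_treatment_dag, build_single_treatment_dag
from .refutation import (
    is_robust,
    refute_placebo,
    refute_random_common_cause,
    refute_subset,
)
from .screening import lag_screen, select_treatments
from .timeseries import (
    EnvSeries,
    VisitSeries,
    deduplicate_visits,
    lag_align,
    read_env_csv,
    read_patient_csv,
    read_visits_csv,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "CohortSummary",
    "summarize_cohort",
    "season_of_month",
    "run_pipeline",
]

SEASONS = ("spring", "summer", "autumn", "winter")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML document."""

    env_csv: str | None = None
    visits_csv: str | None = None
    patients_csv: str | None = None
    synthetic_overrides: dict = field(default_factory=dict)
    followup_window_days: int = 7
    max_lag: int = 6
    alpha: float = 0.05
    selection_rule: str = "all_lags"
    link: str = "identity"
    model_kinds: list[str] = field(
        default_factory=lambda: ["multiple", "single_with_indirect", "single_without_indirect"]
    )
    u_affects_treatments: bool = False
    refute_reps: int = 20
    subset_fraction: float = 0.8
    refute_tolerance: float = 0.1
    attribution_days_per_year: float = 365.0
    seed: int = 0
    out_dir: str = "aircausal_out"

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise PipelineError("max_lag must be >= 0")
        if not (0 < self.alpha < 1):
            raise PipelineError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CohortSummary:
    """Table-1-style cohort description."""

    total: int
    sex_counts: dict[str, int]
    sex_percent: dict[str, float]
    season_counts: dict[str, int]
    season_percent: dict[str, float]
    year_counts: dict[int, int]
    year_percent: dict[int, float]
    age_median: float | None
    age_q1: float | None
    age_q3: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", "", self.total, 100.0)]
        rows += [
            ("sex", k, self.sex_counts[k], self.sex_percent[k]) for k in self.sex_counts
        ]
        rows += [
            ("season", s, self.season_counts[s], self.season_percent[s]) for s in SEASONS
        ]
        rows += [
            ("year", str(y), self.year_counts[y], self.year_percent[y])
            for y in sorted(self.year_counts)
        ]
        return pd.DataFrame(rows, columns=["characteristic", "level", "count", "percent"])


def season_of_month(month: int) -> str:
    """March–May spring, June–August summer, September–November autumn,
    December–February winter."""
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "autumn"
    if month in (12, 1, 2):
        return "winter"
    raise PipelineError(f"invalid month {month}")


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2)


def summarize_cohort(records: pd.DataFrame) -> CohortSummary:
    """Summarize patient-level visit records (Table-1-style margins).

    Requires a ``visit_date`` column; ``sex`` and ``age`` are summarized
    when present.  Percentages are rounded to two decimals; the age quartiles
    use the same linear-interpolation convention as the IQR computation.
    """
    if records is None or len(records) == 0:
        raise PipelineError("summarize_cohort: empty input")
    dates = pd.DatetimeIndex(records["visit_date"])
    total = len(records)
    season = pd.Series([season_of_month(m) for m in dates.month])
    season_counts = {s: int((season == s).sum()) for s in SEASONS}
    years = pd.Series(dates.year)
    year_counts = {int(y): int(c) for y, c in years.value_counts().sort_index().items()}
    if "sex" in records.columns:
        sex_counts = {
            "male": int((records["sex"] == "M").sum()),
            "female": int((records["sex"] == "F").sum()),
        }
    else:
        sex_counts = {}
    if "age" in records.columns:
        ages = np.asarray(records["age"], dtype=float)
        q1, med, q3 = np.percentile(ages, [25.0, 50.0, 75.0])
    else:
        q1 = med = q3 = None
    return CohortSummary(
        total=total,
        sex_counts=sex_counts,
        sex_percent={k: _pct(v, total) for k, v in sex_counts.items()},
        season_counts=season_counts,
        season_percent={k: _pct(v, total) for k, v in season_counts.items()},
        year_counts=year_counts,
        year_percent={k: _pct(v, total) for k, v in year_counts.items()},
        age_median=None if med is None else float(med),
        age_q1=None if q1 is None else float(q1),
        age_q3=None if q3 is None else float(q3),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the in-memory results and a ``status`` key:
    ``ok``, ``not_identified`` (no effect tables written) or ``not_robust``
    (estimates written but the refutation suite failed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed, "status": "ok"}
    bundle: dict = {"manifest": manifest}
    written: dict[str, Path] = {}

    def stage(name: str, **params):
        t0 = time.perf_counter()
        manifest["stages"].append({"stage": name, "params": params, "seconds": None})

        def done():
            manifest["stages"][-1]["seconds"] = round(time.perf_counter() - t0, 4)

        return done

    # ---- data -----------------------------------------------------------
    done = stage("data", seed=config.seed)
    try:
        if config.env_csv:
            env = read_env_csv(config.env_csv)
            if config.patients_csv:
                records = read_patient_csv(config.patients_csv)
                records = deduplicate_visits(records, config.followup_window_days)
                counts = records.groupby("visit_date").size()
                visits = VisitSeries(counts.rename("visits"))
                bundle["cohort"] = summarize_cohort(records)
                bundle["cohort"].to_frame().to_csv(out / "cohort_summary.csv", index=False)
                written["cohort_summary.csv"] = out / "cohort_summary.csv"
            elif config.visits_csv:
                visits = read_visits_csv(config.visits_csv)
            else:
                raise PipelineError("env_csv supplied without visits_csv or patients_csv")
        else:
            cfg = synthetic.default_config(
                **{**config.synthetic_overrides, "seed": config.seed}
            )
            env, visits = synthetic.simulate(cfg)
        env.to_csv(out / "environment.csv")
        visits.to_csv(out / "visits.csv")
        written["environment.csv"] = out / "environment.csv"
        written["visits.csv"] = out / "visits.csv"
    except Exception as exc:
        raise PipelineError(f"stage 'data' failed: {exc}") from exc
    done()
    bundle["env"], bundle["visits"] = env, visits

    # ---- screening ------------------------------------------------------
    done = stage("screening", max_lag=config.max_lag, alpha=config.alpha,
                 rule=config.selection_rule)
    try:
        screen = lag_screen(env, visits, max_lag=config.max_lag, alpha=config.alpha)
        screen.to_csv(out / "lag_screening.csv")
        written["lag_screening.csv"] = out / "lag_screening.csv"
        selected = select_treatments(screen, rule=config.selection_rule)
    except Exception as exc:
        raise PipelineError(f"stage 'screening' failed: {exc}") from exc
    done()
    bundle["screening"], bundle["selected"] = screen, selected

    # ---- modeling + identification + estimation -------------------------
    sweeps: dict[str, pd.DataFrame] = {}
    lags = range(config.max_lag + 1)
    done = stage("estimation", model_kinds=config.model_kinds, link=config.link,
                 u_affects_treatments=config.u_affects_treatments)
    try:
        dags = {}
        if "multiple" in config.model_kinds:
            dags["multiple"] = [build_multiple_treatment_dag(config.u_affects_treatments)]
        from .graphs import TREATMENTS

        for kind, include in (
            ("single_with_indirect", True),
            ("single_without_indirect", False),
        ):
            if kind in config.model_kinds:
                dags[kind] = [
                    build_single_treatment_dag(t, include, config.u_affects_treatments)
                    for t in TREATMENTS
                ]
        identified = {
            kind: all(backdoor_set(d) is not None for d in ds)
            for kind, ds in dags.items()
        }
        if not any(identified.values()):
            manifest["status"] = "not_identified"
        for kind, ds in dags.items():
            if not identified[kind]:
                continue
            parts = [
                run_lag_sweep(env, visits, d, lags=lags, alpha=config.alpha, link=config.link)
                for d in ds
            ]
            sweep = pd.concat(parts, ignore_index=True)
            sweeps[kind] = sweep
            sweep.to_csv(out / f"effects_{kind}_long.csv", index=False)
            sweep_to_wide(sweep).to_csv(out / f"effects_{kind}.csv", index=False)
            written[f"effects_{kind}_long.csv"] = out / f"effects_{kind}_long.csv"
            written[f"effects_{kind}.csv"] = out / f"effects_{kind}.csv"
    except Exception as exc:
        raise PipelineError(f"stage 'estimation' failed: {exc}") from exc
    done()
    bundle["sweeps"] = sweeps

    # ---- refutation (leading single-treatment estimate) ------------------
    refute_kind = next(
        (k for k in ("single_with_indirect", "single_without_indirect") if k in sweeps),
        None,
    )
    if refute_kind is not None:
        done = stage("refutation", reps=config.refute_reps,
                     fraction=config.subset_fraction, tolerance=config.refute_tolerance,
                     seed=config.seed)
        try:
            sweep = sweeps[refute_kind]
            sig = sweep[sweep["significant"] & np.isfinite(sweep["causal_effect"])]
            reports = []
            if not sig.empty:
                best = sig.loc[sig["causal_effect"].idxmax()]
                t, lag = str(best["treatment"]), int(best["lag"])
                dag = build_single_treatment_dag(t, refute_kind == "single_with_indirect")
                adj = sorted(backdoor_set(dag))
                table = lag_align(env, visits, lag)
                common = dict(link=config.link, reps=config.refute_reps, seed=config.seed)
                reports = [
                    refute_random_common_cause(
                        table, t, adj, tolerance=config.refute_tolerance, **common
                    ),
                    refute_placebo(table, t, adj, **common),
                    refute_subset(
                        table, t, adj, fraction=config.subset_fraction,
                        tolerance=config.refute_tolerance, **common
                    ),
                ]
                rows = []
                for rep in reports:
                    for i, v in enumerate(rep.refuted_effects):
                        rows.append(
                            {"method": rep.method, "rep": i, "refuted_effect": v}
                        )
                pd.DataFrame(rows).to_csv(out / "refutation.csv", index=False)
                written["refutation.csv"] = out / "refutation.csv"
                manifest["refutation"] = {
                    "treatment": t,
                    "lag": lag,
                    "reports": [r.summary() for r in reports],
                    "robust": is_robust(reports),
                }
                if not is_robust(reports) and manifest["status"] == "ok":
                    manifest["status"] = "not_robust"
            bundle["refutation"] = reports
        except Exception as exc:
            raise PipelineError(f"stage 'refutation' failed: {exc}") from exc
        done()

    # ---- attribution -----------------------------------------------------
    if refute_kind is not None and refute_kind in sweeps:
        done = stage("attribution", days_per_year=config.attribution_days_per_year)
        try:
            sweep = sweeps[refute_kind]
            years = env.dates.year
            first_year, last_year = int(years.min()), int(years.max())
            obs_red = None
            if first_year != last_year:
                by_year = visits.counts.groupby(visits.dates.year).sum()
                obs_red = float(by_year.loc[first_year] - by_year.loc[last_year])
            results = []
            for pollutant in sorted(set(sweep["treatment"]) - {"pooled"}):
                if pollutant not in env.data.columns:
                    continue
                try:
                    lag, effect = select_attribution_effect(sweep, pollutant, config.alpha)
                except AttributionError:
                    continue
                series = env.data[pollutant]
                start = float(series[years == first_year].mean())
                end = float(series[years == last_year].mean())
                iqr = float(
                    sweep[sweep["treatment"] == pollutant]["iqr"].iloc[0]
                )
                results.append(
                    attribute_pollutant(
                        pollutant, start, end, iqr, effect,
                        days_per_year=config.attribution_days_per_year,
                        observed_reduction=obs_red,
                        unit=env.unit_of(pollutant),
                        expected_unit=env.unit_of(pollutant),
                    )
                )
            if results:
                frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
                frame.to_csv(out / "attribution.csv", index=False)
                written["attribution.csv"] = out / "attribution.csv"
            bundle["attribution"] = results
        except Exception as exc:
            raise PipelineError(f"stage 'attribution' failed: {exc}") from exc
        done()

    manifest["outputs"] = {name: _sha256(p) for name, p in written.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["status"] = manifest["status"]
    return bundle
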