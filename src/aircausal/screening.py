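"""Lagged Spearman screening of environmental variables against visit counts.

Daily counts are far from normal, so association screening uses the Spearman
rank correlation.  Each variable is tested against the outcome at lags 0
through ``max_lag`` (exposure ``lag`` days before the outcome), giving a
variable × lag grid of (rs, p) cells; variables are then promoted to
candidate treatments either when any lag is significant or when every lag is.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import EnvSeries, VisitSeries, lag_align

__all__ = ["ScreeningError", "LagCorrelationResult", "spearman", "lag_screen", "select_treatments"]


class ScreeningError(ValueError):
    """Invalid screening input."""


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``method='t'`` uses the t approximation on n−2 degrees of freedom
    (appropriate at the study's n ≈ 2900); ``method='exact'`` enumerates all
    rank permutations (n ≤ 8 only) and returns the exact two-sided tail
    probability of |rs|.  Ties are average-ranked.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScreeningError("spearman requires two equal-length vectors")
    n = x.size
    if n < 4:
        raise ScreeningError("spearman requires at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ScreeningError("spearman is undefined for a constant vector")
    if method == "t":
        rs, p = stats.spearmanr(x, y)
        return float(rs), float(p)
    if method == "exact":
        if n > 8:
            raise ScreeningError("exact permutation p-value limited to n <= 8")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = float(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        total = 0
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            hits += abs(r) >= abs(observed) - 1e-12
            total += 1
        return observed, hits / total
    raise ScreeningError(f"unknown method {method!r}")


@dataclass
class LagCorrelationResult:
    """Variable × lag grid of Spearman associations with the outcome.

    ``frame`` is long-format with columns variable, lag, rs, p, n,
    significant (at ``alpha``).
    """

    frame: pd.DataFrame
    max_lag: int
    alpha: float

    def cell(self, variable: str, lag: int) -> tuple[float, float, int]:
        row = self.frame[(self.frame["variable"] == variable) & (self.frame["lag"] == lag)]
        if row.empty:
            raise ScreeningError(f"no cell for ({variable!r}, lag {lag})")
        r = row.iloc[0]
        return float(r["rs"]), float(r["p"]), int(r["n"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def lag_screen(
    env: EnvSeries,
    visits: VisitSeries,
    max_lag: int = 6,
    alpha: float = 0.05,
) -> LagCorrelationResult:
    """Spearman grid over all variables × lags 0..max_lag."""
    if max_lag < 0:
        raise ScreeningError("max_lag must be non-negative")
    rows = []
    for lag in range(max_lag + 1):
        table = lag_align(env, visits, lag)  # raises if the lag exceeds the span
        y = table["visits"].to_numpy()
        for var in env.variables:
            rs, p = spearman(table[var].to_numpy(), y)
            rows.append(
                {
                    "variable": var,
                    "lag": lag,
                    "rs": rs,
                    "p": p,
                    "n": len(table),
                    "significant": bool(p < alpha),
                }
            )
    frame = pd.DataFrame(rows).sort_values(["variable", "lag"], kind="stable").reset_index(drop=True)
    return LagCorrelationResult(frame=frame, max_lag=max_lag, alpha=alpha)


def select_treatments(result: LagCorrelationResult, rule: str = "all_lags") -> list[str]:
    """Promote variables to candidate treatments.

    ``any_lag`` selects variables significant at one or more lags; the
    stricter ``all_lags`` (the default) requires significance at every lag
    0..max_lag.  Output order follows the grid's variable order.
    """
    if rule not in ("any_lag", "all_lags"):
        raise ScreeningError(f"unknown selection rule {rule!r}")
    agg = result.frame.groupby("variable", sort=False)["significant"].agg(["any", "all"])
    key = "any" if rule == "any_lag" else "all"
    return [v for v in agg.index if bool(agg.loc[v, key])]
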