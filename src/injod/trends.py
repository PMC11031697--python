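"""Multiyear relative percent change in rates, with CIs, vs the nation.

The relative percent change between two years is
(rate_end - rate_start) / rate_start x 100.  Its confidence interval
uses a delta-method normal approximation on log(rate_end/rate_start):
each rate's standard error is back-computed from its CI half-width
divided by 1.96, converted to the log scale, and the two years are
treated as independent.  States are then classified against the
national trend: "faster" when the state's CI lies wholly above the
national point change, "slower" when wholly below, otherwise
"similar"; a state suppressed in either endpoint year has its trend
suppressed too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class TrendComparison(str, Enum):
    FASTER = "faster"
    SLOWER = "slower"
    SIMILAR = "similar"
    SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class TrendResult:
    state: str
    year_start: int
    year_end: int
    pct_change: float | None
    pct_change_lo: float | None
    pct_change_hi: float | None
    vs_national: TrendComparison


def percent_change(rate_start: float, rate_end: float) -> float:
    """Relative percent change; undefined (error) when the start rate is 0."""
    if rate_start <= 0:
        raise ValueError(f"start rate must be positive, got {rate_start}")
    return (rate_end - rate_start) / rate_start * 100.0


def percent_change_ci(
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    z: float = Z_95,
) -> tuple[float, float]:
    """Delta-method CI for the relative percent change.

    ``start`` and ``end`` are (point, ci_lo, ci_hi) rate triples.  Each
    rate's SE is (hi - lo) / 2 / z; the variance of the log ratio is the
    sum of the squared log-scale SEs.  Degenerate (zero-width) inputs
    collapse to the point change.  A non-finite log-scale SE (zero
    point rate) falls back to the endpoint-combination interval.
    """
    r0, lo0, hi0 = start
    r1, lo1, hi1 = end
    if r0 <= 0:
        raise ValueError("start rate must be positive")
    se0 = (hi0 - lo0) / 2.0 / z
    se1 = (hi1 - lo1) / 2.0 / z
    if se0 == 0 and se1 == 0:
        pc = percent_change(r0, r1)
        return pc, pc
    if se0 < 0 or se1 < 0 or r1 <= 0:
        logger.warning(
            "degenerate CI inputs (start %s, end %s); using endpoint combination",
            start,
            end,
        )
        return (lo1 / hi0 - 1.0) * 100.0, (hi1 / lo0 - 1.0) * 100.0
    log_ratio = math.log(r1 / r0)
    se_log = math.hypot(se0 / r0, se1 / r1)
    lo = (math.exp(log_ratio - z * se_log) - 1.0) * 100.0
    hi = (math.exp(log_ratio + z * se_log) - 1.0) * 100.0
    return lo, hi


def _rate_triple(row: pd.Series) -> tuple[float, float, float]:
    return float(row["rate"]), float(row["rate_lo"]), float(row["rate_hi"])


def state_trend(
    estimates: pd.DataFrame, state: str, year_start: int, year_end: int
) -> TrendResult | None:
    """Percent-change trend for one state; None when an endpoint is absent."""
    rows = estimates[estimates["state"] == state]
    s = rows[rows["year"] == year_start]
    e = rows[rows["year"] == year_end]
    if s.empty or e.empty:
        return None
    s, e = s.iloc[0], e.iloc[0]
    if bool(s.get("suppressed", False)) or bool(e.get("suppressed", False)):
        return TrendResult(
            state, year_start, year_end, None, None, None, TrendComparison.SUPPRESSED
        )
    if s["rate"] <= 0:
        logger.warning("state %s has zero %d rate; trend undefined", state, year_start)
        return TrendResult(
            state, year_start, year_end, None, None, None, TrendComparison.SUPPRESSED
        )
    pc = percent_change(s["rate"], e["rate"])
    lo, hi = percent_change_ci(_rate_triple(s), _rate_triple(e))
    return TrendResult(state, year_start, year_end, pc, lo, hi, TrendComparison.SIMILAR)


def compare_to_national(
    estimates: pd.DataFrame,
    national: pd.DataFrame,
    year_start: int,
    year_end: int,
    mode: str = "ci_vs_point",
) -> pd.DataFrame:
    """Trend table for every state, classified against the national trend.

    ``mode`` "ci_vs_point" (default) calls a state faster/slower only
    when its whole CI lies above/below the national point change;
    "point_vs_point" compares point estimates directly.
    """
    nat_rows = national[
        (national["year"] == year_start) | (national["year"] == year_end)
    ]
    nat = state_trend(nat_rows, nat_rows["state"].iloc[0], year_start, year_end)
    if nat is None or nat.pct_change is None:
        raise ValueError("national trend unavailable for the requested years")

    records = []
    for state in sorted(estimates["state"].unique()):
        tr = state_trend(estimates, state, year_start, year_end)
        if tr is None:
            continue
        if tr.pct_change is None:
            cmp = TrendComparison.SUPPRESSED
        elif mode == "point_vs_point":
            cmp = (
                TrendComparison.FASTER
                if tr.pct_change > nat.pct_change
                else TrendComparison.SLOWER
                if tr.pct_change < nat.pct_change
                else TrendComparison.SIMILAR
            )
        elif mode == "ci_vs_point":
            if tr.pct_change_lo > nat.pct_change:
                cmp = TrendComparison.FASTER
            elif tr.pct_change_hi < nat.pct_change:
                cmp = TrendComparison.SLOWER
            else:
                cmp = TrendComparison.SIMILAR
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")
        records.append(
            {
                "state": state,
                "year_start": year_start,
                "year_end": year_end,
                "pct_change": tr.pct_change,
                "pct_change_lo": tr.pct_change_lo,
                "pct_change_hi": tr.pct_change_hi,
                "vs_national": cmp.value,
            }
        )
    out = pd.DataFrame(records)
    out.attrs["national"] = nat
    return out
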