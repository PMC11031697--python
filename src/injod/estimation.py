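"""Injection-involved death estimates, rates, CIs, and suppression.

The point estimate for a state-year is the sum over drugs and strata of
(probability of injection) x (allocated deaths); OTHER_T deaths carry
probability zero because injection probabilities exist only for the
five treatment drug groups, which makes the estimate conservative.
Interval endpoints propagate by summing each cell's Clopper-Pearson
endpoint times its death count (death counts are treated as fixed);
a Monte-Carlo mode sampling each cell's probability from a Beta is
available for sensitivity.

State-years are suppressed when fewer than 50 admissions reported a
drug of interest, or when the missing-route fraction exceeds 15%, or
when the state reported no treatment data at all.  Suppressed states
still contribute to the national aggregate; non-reporting states are
excluded from the national rate denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding import STRATUM_COLS, TREATMENT_DRUGS
from .injection_probability import ProbabilityLookup

logger = logging.getLogger(__name__)

STRATUM = list(STRATUM_COLS)
NATIONAL = "US"


class SuppressionReason(str, Enum):
    NONE = "none"
    ADMISSIONS_LT_50 = "admissions_lt_50"
    MISSING_GT_15PCT = "missing_gt_15pct"
    NO_TEDS_DATA = "no_teds_data"


@dataclass(frozen=True)
class SuppressionRules:
    """Thresholds for withholding a state-year estimate."""

    min_admissions: int = 50
    max_missing_fraction: float = 0.15  # strict: suppress when fraction > this


def compute_rate(deaths: float, population: float) -> float:
    """Deaths per 100,000 person-years."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    return deaths / population * 100_000.0


def estimate_injection_deaths(
    allocated: pd.DataFrame,
    probabilities: ProbabilityLookup,
    ci_mode: str = "endpoint",
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Injection-involved overdose deaths per state-year, with CI.

    Parameters
    ----------
    allocated
        Output of :func:`injod.death_allocation.tabulate_deaths`.
    probabilities
        Fallback-ladder lookup built from the admissions data.
    ci_mode
        "endpoint" sums CI endpoints times deaths (conservative
        default); "mc" samples each cell's probability from
        Beta(x+1, n-x+1) and takes the 2.5/97.5 percentiles of the
        resulting totals.

    Returns
    -------
    One row per state-year: deaths_point/lo/hi, pct_of_overdoses with
    CI, n_overdose, and the share of the estimate that came from
    fallback-pooled probability cells.
    """
    cells = allocated[
        allocated["category"].isin([d.value for d in TREATMENT_DRUGS])
    ].rename(columns={"category": "drug"})
    cells = cells[cells["count"] > 0].copy()
    cells = probabilities.attach(cells)

    unavailable = cells["p_hat"].isna()
    if unavailable.any():
        n_bad = int(unavailable.sum())
        logger.warning(
            "%d death cells have no injection probability at any pooling "
            "level; they contribute no injection-involved deaths",
            n_bad,
        )
        cells = cells[~unavailable].copy()

    cells["deaths_point"] = cells["p_hat"] * cells["count"]
    cells["deaths_lo"] = cells["ci_lo"] * cells["count"]
    cells["deaths_hi"] = cells["ci_hi"] * cells["count"]
    cells["fallback_deaths"] = np.where(
        cells["fallback_level"] != "cell", cells["deaths_point"], 0.0
    )

    by_sy = (
        cells.groupby(["state", "year"], observed=True)[
            ["deaths_point", "deaths_lo", "deaths_hi", "fallback_deaths"]
        ]
        .sum()
        .reset_index()
    )

    raw = (
        allocated.groupby(["state", "year"], observed=True)["count"]
        .sum()
        .rename("n_overdose")
        .reset_index()
    )
    out = raw.merge(by_sy, on=["state", "year"], how="left").fillna(
        {"deaths_point": 0.0, "deaths_lo": 0.0, "deaths_hi": 0.0, "fallback_deaths": 0.0}
    )

    if ci_mode == "mc":
        lo, hi = _mc_interval(cells, rng or np.random.default_rng(), n_mc)
        out = out.drop(columns=["deaths_lo", "deaths_hi"]).merge(
            pd.DataFrame(
                {"state": lo.index.get_level_values(0),
                 "year": lo.index.get_level_values(1),
                 "deaths_lo": lo.values, "deaths_hi": hi.values}
            ),
            on=["state", "year"],
            how="left",
        ).fillna({"deaths_lo": 0.0, "deaths_hi": 0.0})
    elif ci_mode != "endpoint":
        raise ValueError(f"unknown ci_mode {ci_mode!r}")

    for col, pref in (
        ("pct_of_overdoses", "deaths_point"),
        ("pct_lo", "deaths_lo"),
        ("pct_hi", "deaths_hi"),
    ):
        out[col] = np.where(
            out["n_overdose"] > 0, out[pref] / out["n_overdose"] * 100.0, np.nan
        )
    out["fallback_share"] = np.where(
        out["deaths_point"] > 0, out["fallback_deaths"] / out["deaths_point"], 0.0
    )
    return out.drop(columns=["fallback_deaths"])


def _mc_interval(cells: pd.DataFrame, rng: np.random.Generator, n_mc: int):
    """Percentile interval from Beta(x+1, n-x+1) draws per probability cell."""
    a = cells["n_injection"].to_numpy(float) + 1.0
    b = (cells["n_route_known"] - cells["n_injection"]).to_numpy(float) + 1.0
    counts = cells["count"].to_numpy(float)
    draws = stats.beta.rvs(a[:, None], b[:, None], size=(len(a), n_mc),
                           random_state=rng)
    totals = pd.DataFrame(draws * counts[:, None]).groupby(
        [cells["state"].values, cells["year"].values]
    ).sum()
    lo = totals.quantile(0.025, axis=1)
    hi = totals.quantile(0.975, axis=1)
    return lo, hi


def attach_population(estimates: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Merge state-year population totals and compute rates per 100,000."""
    pop_sy = (
        population.groupby(["state", "year"], observed=True)["population"]
        .sum()
        .reset_index()
    )
    out = estimates.merge(pop_sy, on=["state", "year"], how="left")
    if out["population"].isna().any():
        bad = out.loc[out["population"].isna(), ["state", "year"]]
        raise ValueError(
            "missing population for state-years: "
            + ", ".join(f"{s}-{y}" for s, y in bad.itertuples(index=False))
        )
    for col, src in (("rate", "deaths_point"), ("rate_lo", "deaths_lo"),
                     ("rate_hi", "deaths_hi")):
        out[col] = out[src] / out["population"] * 100_000.0
    return out


def apply_suppression(
    estimates: pd.DataFrame,
    missingness: pd.DataFrame,
    rules: SuppressionRules = SuppressionRules(),
) -> pd.DataFrame:
    """Flag state-years that fail the admission-quality thresholds.

    A state-year is suppressed when the number of admissions reporting
    any drug of interest is below ``rules.min_admissions``, when the
    missing-route fraction strictly exceeds ``rules.max_missing_fraction``,
    or when no treatment data exist for that state-year at all.
    """
    m = missingness[["state", "year", "n_admissions", "missing_fraction"]]
    out = estimates.merge(m, on=["state", "year"], how="left")

    no_data = out["n_admissions"].isna()
    too_few = out["n_admissions"] < rules.min_admissions
    too_missing = out["missing_fraction"] > rules.max_missing_fraction

    out["suppression_reason"] = SuppressionReason.NONE.value
    out.loc[too_missing, "suppression_reason"] = (
        SuppressionReason.MISSING_GT_15PCT.value
    )
    out.loc[too_few, "suppression_reason"] = SuppressionReason.ADMISSIONS_LT_50.value
    out.loc[no_data, "suppression_reason"] = SuppressionReason.NO_TEDS_DATA.value
    out["suppressed"] = out["suppression_reason"] != SuppressionReason.NONE.value
    return out


def national_aggregate(
    estimates: pd.DataFrame,
    population: pd.DataFrame,
    reporting_states: Mapping[int, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """National totals per year over reporting states.

    Suppressed state-years still count toward the national numerator and
    denominator; states with no treatment data at all (non-reporting)
    are excluded, including from the population denominator and from the
    percentage-of-overdose-deaths denominator.

    ``reporting_states`` defaults to states whose suppression reason is
    anything but "no_teds_data" in that year.
    """
    pop_sy = (
        population.groupby(["state", "year"], observed=True)["population"]
        .sum()
        .reset_index()
    )
    rows = []
    for year, sub in estimates.groupby("year", observed=True):
        if reporting_states is not None:
            rep = set(reporting_states[int(year)])
        else:
            rep = set(
                sub.loc[
                    sub["suppression_reason"] != SuppressionReason.NO_TEDS_DATA.value,
                    "state",
                ]
            )
        sub = sub[sub["state"].isin(rep)]
        pop = pop_sy[(pop_sy["year"] == year) & (pop_sy["state"].isin(rep))][
            "population"
        ].sum()
        point = sub["deaths_point"].sum()
        lo = sub["deaths_lo"].sum()
        hi = sub["deaths_hi"].sum()
        n_od = sub["n_overdose"].sum()
        rows.append(
            {
                "state": NATIONAL,
                "year": year,
                "n_overdose": n_od,
                "deaths_point": point,
                "deaths_lo": lo,
                "deaths_hi": hi,
                "pct_of_overdoses": point / n_od * 100.0 if n_od else np.nan,
                "pct_lo": lo / n_od * 100.0 if n_od else np.nan,
                "pct_hi": hi / n_od * 100.0 if n_od else np.nan,
                "population": pop,
                "rate": compute_rate(point, pop) if pop else np.nan,
                "rate_lo": compute_rate(lo, pop) if pop else np.nan,
                "rate_hi": compute_rate(hi, pop) if pop else np.nan,
                "suppressed": False,
                "suppression_reason": SuppressionReason.NONE.value,
            }
        )
    return pd.DataFrame(rows)
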