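"""Stratified injection probabilities from treatment admissions.

For each (state, year, drug, stratum) cell the probability of injection
is the share of admissions reporting that drug, with a known route of
administration, whose usual route is injection.  Exact (Clopper-Pearson)
binomial intervals are attached to every cell.  Cells with no
route-known admissions are filled by a pooling ladder — state-year-drug,
then national year-drug-stratum, then national year-drug — with the
level used recorded in ``fallback_level``.

The module also produces the national per-year injection ranking of the
five drugs (used to resolve polydrug deaths) and per-state-year
route-of-administration missingness summaries (used for suppression).
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .coding import CANONICAL_DRUG_ORDER, STRATUM_COLS, TREATMENT_DRUGS, DrugType

logger = logging.getLogger(__name__)

STRATUM = list(STRATUM_COLS)


class FallbackLevel(str, Enum):
    CELL = "cell"
    STATE_YEAR_DRUG = "state_year_drug"
    NATIONAL_YEAR_DRUG_STRATUM = "national_year_drug_stratum"
    NATIONAL_YEAR_DRUG = "national_year_drug"
    UNAVAILABLE = "unavailable"


def clopper_pearson(x, n, alpha: float = 0.05):
    """Exact equal-tailed binomial confidence interval.

    Beta-quantile form: lo = B(alpha/2; x, n-x+1) (0 when x=0) and
    hi = B(1-alpha/2; x+1, n-x) (1 when x=n).  Accepts scalars or
    arrays; n must be >= 1 everywhere (an empty cell is a fallback
    signal, not an interval).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("clopper_pearson requires n >= 1 (empty cell -> fallback)")
    if np.any((x < 0) | (x > n)):
        raise ValueError("require 0 <= x <= n")
    with np.errstate(invalid="ignore"):
        lo = np.where(x == 0, 0.0, stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = np.where(x == n, 1.0, stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def _require_long_admissions(admissions: pd.DataFrame) -> None:
    needed = {"state", "year", *STRATUM, "drug", "route"}
    missing = needed - set(admissions.columns)
    if missing:
        raise ValueError(f"admissions table missing columns: {sorted(missing)}")


def _cell_counts(admissions: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """x (injection) and n (route known) per grouping key."""
    known = admissions[admissions["route"] != "missing"]
    grp = known.groupby(keys, observed=True)
    out = grp.agg(
        n_route_known=("route", "size"),
        n_injection=("route", lambda r: int((r == "injection").sum())),
    ).reset_index()
    return out


def estimate_probabilities(
    admissions: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Injection probability table at the finest (cell) level.

    Parameters
    ----------
    admissions
        Long-format normalized admissions: one row per (record, drug of
        interest) with columns state, year, sex, age_group,
        race_ethnicity, drug, route ("injection"/"other"/"missing").

    Returns
    -------
    DataFrame with one row per observed (state, year, drug, stratum)
    cell that has at least one route-known admission: counts, p_hat and
    the Clopper-Pearson interval, fallback_level == "cell".
    """
    _require_long_admissions(admissions)
    cells = _cell_counts(admissions, ["state", "year", "drug"] + STRATUM)
    cells["p_hat"] = cells["n_injection"] / cells["n_route_known"]
    cells["ci_lo"], cells["ci_hi"] = clopper_pearson(
        cells["n_injection"], cells["n_route_known"], alpha
    )
    cells["fallback_level"] = FallbackLevel.CELL.value
    return cells


class ProbabilityLookup:
    """Fallback ladder over pooled injection-probability tables.

    Level 1: the exact (state, year, drug, stratum) cell.
    Level 2: state-year-drug pooled over strata.
    Level 3: national year-drug-stratum.
    Level 4: national year-drug.
    A query that misses every level is returned as unavailable (NaN).
    """

    def __init__(self, admissions: pd.DataFrame, alpha: float = 0.05):
        _require_long_admissions(admissions)
        self.alpha = alpha
        self.cell = estimate_probabilities(admissions, alpha)
        self._pools = [
            (FallbackLevel.CELL, ["state", "year", "drug"] + STRATUM, self.cell),
            (
                FallbackLevel.STATE_YEAR_DRUG,
                ["state", "year", "drug"],
                self._pooled(admissions, ["state", "year", "drug"]),
            ),
            (
                FallbackLevel.NATIONAL_YEAR_DRUG_STRATUM,
                ["year", "drug"] + STRATUM,
                self._pooled(admissions, ["year", "drug"] + STRATUM),
            ),
            (
                FallbackLevel.NATIONAL_YEAR_DRUG,
                ["year", "drug"],
                self._pooled(admissions, ["year", "drug"]),
            ),
        ]

    def pooled_table(self, level: "FallbackLevel | str") -> pd.DataFrame:
        """The pooled x/n/p̂ table backing one ladder level."""
        level = FallbackLevel(level)
        for lv, _, table in self._pools:
            if lv == level:
                return table
        raise KeyError(level)

    def _pooled(self, admissions: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        pooled = _cell_counts(admissions, keys)
        pooled["p_hat"] = pooled["n_injection"] / pooled["n_route_known"]
        pooled["ci_lo"], pooled["ci_hi"] = clopper_pearson(
            pooled["n_injection"], pooled["n_route_known"], self.alpha
        )
        return pooled

    def attach(self, cells: pd.DataFrame) -> pd.DataFrame:
        """Attach p_hat/ci_lo/ci_hi/fallback_level to query rows.

        ``cells`` needs columns state, year, drug, sex, age_group,
        race_ethnicity.  Rows that miss every pooling level come back
        with NaN probabilities and fallback_level == "unavailable".
        """
        out = cells.reset_index(drop=True).copy()
        value_cols = ("p_hat", "ci_lo", "ci_hi", "n_route_known", "n_injection")
        for col in value_cols:
            out[col] = np.nan
        out["fallback_level"] = FallbackLevel.UNAVAILABLE.value
        for level, keys, table in self._pools:
            unresolved = out["p_hat"].isna()
            if not unresolved.any():
                break
            sub = out.loc[unresolved, keys].reset_index()
            merged = sub.merge(
                table[keys + list(value_cols)], on=keys, how="left"
            ).set_index("index")
            hit = merged["p_hat"].notna()
            idx = merged.index[hit]
            for col in value_cols:
                out.loc[idx, col] = merged.loc[hit, col]
            out.loc[idx, "fallback_level"] = level.value
        return out


def overall_injection_ranking(
    admissions: pd.DataFrame, year: int | None = None
) -> list[DrugType]:
    """National injection ranking of the five drugs, most-injected first.

    Pools numerators and denominators nationally (for one year if given,
    else over all years).  Ties, and drugs with no route-known
    admissions, fall back to the canonical drug order; absent drugs rank
    after all drugs with data.
    """
    _require_long_admissions(admissions)
    sub = admissions if year is None else admissions[admissions["year"] == year]
    pooled = _cell_counts(sub, ["drug"]).set_index("drug")
    canon_rank = {d.value: i for i, d in enumerate(CANONICAL_DRUG_ORDER)}

    def sort_key(drug: DrugType):
        if drug.value in pooled.index and pooled.loc[drug.value, "n_route_known"] > 0:
            pct = pooled.loc[drug.value, "n_injection"] / pooled.loc[
                drug.value, "n_route_known"
            ]
            return (0, -pct, canon_rank[drug.value])
        logger.warning(
            "drug %s has no route-known admissions%s; ranked last",
            drug.value,
            f" in {year}" if year is not None else "",
        )
        return (1, 0.0, canon_rank[drug.value])

    return sorted(TREATMENT_DRUGS, key=sort_key)


def missingness_summary(admissions: pd.DataFrame) -> pd.DataFrame:
    """Route-of-administration missingness per state-year.

    Pooled over the five drugs of interest: the fraction of substance
    reports with a missing route, plus the total number of admissions
    reporting any drug of interest (the <50 suppression denominator
    counts admissions, so records are deduplicated for ``n_admissions``).
    """
    _require_long_admissions(admissions)
    df = admissions.copy()
    df["missing_route"] = (df["route"] == "missing").astype(int)
    grp = df.groupby(["state", "year"], observed=True)
    out = grp.agg(
        n_reporting_drug=("drug", "size"),
        n_missing_route=("missing_route", "sum"),
    ).reset_index()
    if "record_id" in df.columns:
        n_adm = (
            df.groupby(["state", "year"], observed=True)["record_id"]
            .nunique()
            .rename("n_admissions")
            .reset_index()
        )
        out = out.merge(n_adm, on=["state", "year"])
    else:
        out["n_admissions"] = out["n_reporting_drug"]
    out["missing_fraction"] = out["n_missing_route"] / out["n_reporting_drug"]
    return out
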