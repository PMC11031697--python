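"""Assign overdose deaths to drug categories and redistribute T50.9-only deaths.

Each adult overdose death is assigned to exactly one of six categories:
the five specific drug groups or OTHER_T.  Polydrug deaths (multiple
specific T-codes) take the listed drug with the highest overall
injection percentage, as ranked from the treatment data.  Deaths whose
only T-code is T50.9 ("unspecified") are then redistributed across the
six categories proportionally to the non-missing category distribution
within (state, year, stratum), falling back to the national
(year, stratum) distribution, producing fractional counts that conserve
the raw overdose total of every cell.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import (
    DEATH_CATEGORIES,
    STRATUM_COLS,
    DrugType,
    map_tcodes_to_categories,
)

logger = logging.getLogger(__name__)

STRATUM = list(STRATUM_COLS)
CELL = ["state", "year"] + STRATUM


def assign_category(
    tcodes: Sequence[str], ranking: Sequence[DrugType]
) -> DrugType:
    """Single category for one death, given the injection ranking.

    Among the categories implied by the T-codes, the highest-ranked of
    the five specific drugs wins; OTHER_T only if no specific drug is
    listed; UNSPECIFIED iff T50.9 is the only drug-poisoning code.
    """
    categories = map_tcodes_to_categories(tcodes)
    if categories == {DrugType.UNSPECIFIED}:
        return DrugType.UNSPECIFIED
    rank = {d: i for i, d in enumerate(ranking)}
    specific = [c for c in categories if c in rank]
    if specific:
        return min(specific, key=rank.__getitem__)
    return DrugType.OTHER_T


def redistribute_unspecified(
    counts: Mapping[DrugType, float],
    unspecified: float,
    fallback_shares: Mapping[DrugType, float] | None = None,
) -> dict[DrugType, float]:
    """Spread an unspecified count over the six categories proportionally.

    ``counts`` is the non-missing distribution at the pooling key; when
    its total is zero the ``fallback_shares`` distribution is used; if
    that is also empty the whole unspecified mass goes to OTHER_T with a
    warning.  Fractional outputs are intentional — rounding happens only
    at report time, so cell totals are conserved exactly.
    """
    out = {c: float(counts.get(c, 0.0)) for c in DEATH_CATEGORIES}
    if unspecified == 0:
        return out
    total = sum(counts.get(c, 0.0) for c in DEATH_CATEGORIES)
    if total > 0:
        shares = {c: counts.get(c, 0.0) / total for c in DEATH_CATEGORIES}
    elif fallback_shares and sum(fallback_shares.values()) > 0:
        ft = sum(fallback_shares.get(c, 0.0) for c in DEATH_CATEGORIES)
        shares = {c: fallback_shares.get(c, 0.0) / ft for c in DEATH_CATEGORIES}
    else:
        logger.warning(
            "no non-missing category distribution at any pooling level; "
            "%g unspecified deaths assigned to OTHER_T",
            unspecified,
        )
        shares = {c: 0.0 for c in DEATH_CATEGORIES}
        shares[DrugType.OTHER_T] = 1.0
    for c in DEATH_CATEGORIES:
        out[c] += unspecified * shares[c]
    return out


def _assign_categories_vectorized(
    deaths: pd.DataFrame, ranking_by_year: Mapping[int, Sequence[DrugType]]
) -> pd.Series:
    """Category per death row; tcodes column holds tuples of code strings."""
    keys = pd.Series(
        list(zip(deaths["year"], deaths["tcodes"].map(tuple))), index=deaths.index
    )
    cache: dict[tuple[int, tuple[str, ...]], str] = {}

    def categorize(key: tuple[int, tuple[str, ...]]) -> str:
        if key not in cache:
            year, tcodes = key
            cache[key] = assign_category(tcodes, ranking_by_year[year]).value
        return cache[key]

    return keys.map(categorize)


def tabulate_deaths(
    deaths: pd.DataFrame,
    ranking_by_year: Mapping[int, Sequence[DrugType]],
    redistribute: bool = True,
) -> pd.DataFrame:
    """Allocated death counts per (state, year, stratum, category).

    Parameters
    ----------
    deaths
        One row per adult overdose death with columns state, year, sex,
        age_group, race_ethnicity and tcodes (sequence of code strings).
    ranking_by_year
        Injection ranking of the five drugs per year (polydrug rule).
    redistribute
        When True (default), T50.9-only deaths are redistributed; the
        returned counts are fractional and conserve per-cell totals.

    Returns
    -------
    Long DataFrame with CELL columns plus ``category`` (six values),
    ``count`` (possibly fractional), and per-cell bookkeeping columns
    ``n_overdose`` (raw total) and ``n_unspecified_input``.
    """
    if deaths.empty:
        return pd.DataFrame(
            columns=CELL + ["category", "count", "n_overdose", "n_unspecified_input"]
        )
    df = deaths.copy()
    df["category"] = _assign_categories_vectorized(df, ranking_by_year)

    raw = (
        df.groupby(CELL + ["category"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    wide = raw.pivot_table(
        index=CELL, columns="category", values="count", fill_value=0, observed=True
    )
    for c in DEATH_CATEGORIES:
        if c.value not in wide.columns:
            wide[c.value] = 0.0
    if DrugType.UNSPECIFIED.value not in wide.columns:
        wide[DrugType.UNSPECIFIED.value] = 0.0
    wide = wide.astype(float)

    cat_cols = [c.value for c in DEATH_CATEGORIES]
    unspec = wide[DrugType.UNSPECIFIED.value]
    n_overdose = wide[cat_cols].sum(axis=1) + unspec

    if redistribute:
        # national (year, stratum) non-missing distribution as fallback
        nat = wide.groupby(["year"] + STRATUM, observed=True)[cat_cols].sum()
        rows = []
        for idx, row in wide.iterrows():
            counts = {c: row[c.value] for c in DEATH_CATEGORIES}
            u = row[DrugType.UNSPECIFIED.value]
            if u > 0 and sum(counts.values()) == 0:
                nat_key = (idx[1],) + tuple(idx[2:])  # (year, sex, age, race)
                fb_row = nat.loc[nat_key] if nat_key in nat.index else None
                fallback = (
                    {c: fb_row[c.value] for c in DEATH_CATEGORIES}
                    if fb_row is not None
                    else None
                )
            else:
                fallback = None
            rows.append(redistribute_unspecified(counts, u, fallback))
        alloc = pd.DataFrame(
            [{c.value: r[c] for c in DEATH_CATEGORIES} for r in rows],
            index=wide.index,
        )
    else:
        alloc = wide[cat_cols].copy()
        alloc[DrugType.UNSPECIFIED.value] = unspec

    alloc["n_overdose"] = n_overdose
    alloc["n_unspecified_input"] = unspec
    out = alloc.reset_index().melt(
        id_vars=CELL + ["n_overdose", "n_unspecified_input"],
        var_name="category",
        value_name="count",
    )
    return out.sort_values(CELL + ["category"]).reset_index(drop=True)


def category_percentages(allocated: pd.DataFrame) -> pd.DataFrame:
    """Percentage of overdose deaths in each category per state-year.

    The Table S2 analogue: shares of the six post-redistribution
    categories among all overdose deaths of the state-year.
    """
    by_sy = (
        allocated.groupby(["state", "year", "category"], observed=True)["count"]
        .sum()
        .reset_index()
    )
    totals = by_sy.groupby(["state", "year"], observed=True)["count"].transform("sum")
    by_sy["pct_of_overdose_deaths"] = np.where(
        totals > 0, by_sy["count"] / totals * 100.0, np.nan
    )
    return by_sy
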