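"""Published state-level summary tables and arithmetic cross-checks.

The study's headline numbers were produced from restricted microdata
(treatment-admission and vital-statistics line files) that cannot be
redistributed, so the raw analysis is not reproducible at desk scale.
What can be checked is internal arithmetic: the package ships the
published 2020 state summary table and national summary rates as small
CSV inputs, and re-derives the quantities that are functions of them —
the national rate over the reporting-state population, the median and
range of state rates, the share of the national estimate concentrated
in the largest states, and the 2010-2020 national percent change — with
the same operations the pipeline uses on synthetic data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .estimation import compute_rate
from .trends import percent_change, percent_change_ci


def _load(name: str) -> pd.DataFrame:
    with resources.files("injod.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_state_estimates_2020() -> pd.DataFrame:
    """Published 2020 state table: population, overdose deaths, estimates.

    ``status`` distinguishes states with estimates ("ok"), suppressed
    states, states that reported no treatment data ("nonreporting"),
    and the national row.
    """
    return _load("published_state_estimates_2020.csv")


def load_national_summary() -> pd.DataFrame:
    """Published national injection-involved estimates for 2000/2010/2020."""
    return _load("published_national_summary.csv")


def derived_quantities() -> dict[str, float]:
    """Re-derive the published quantities that follow arithmetically.

    Returns a flat mapping of descriptive names to values on the scale
    the published tables print (percentages as percent, rates per
    100,000).
    """
    table = load_state_estimates_2020()
    states = table[table["status"] != "national"]
    national = table[table["status"] == "national"].iloc[0]
    ok = states[states["status"] == "ok"]

    nonreporting_pop = states.loc[
        states["status"] == "nonreporting", "population"
    ].sum()
    nonreporting_od = states.loc[
        states["status"] == "nonreporting", "overdose_deaths"
    ].sum()
    reporting_pop = national["population"] - nonreporting_pop
    reporting_od = national["overdose_deaths"] - nonreporting_od

    out: dict[str, float] = {}
    out["national_injection_deaths_2020"] = float(national["deaths"])
    out["national_rate_per_100k_2020"] = compute_rate(
        national["deaths"], reporting_pop
    )
    out["national_pct_of_overdoses_2020"] = (
        national["deaths"] / reporting_od * 100.0
    )
    out["pct_overdoses_in_reporting_states_2020"] = (
        reporting_od / national["overdose_deaths"] * 100.0
    )
    out["n_states_with_estimates_2020"] = float(len(ok))
    out["median_state_rate_2020"] = float(np.median(ok["rate"]))
    out["min_state_rate_2020"] = float(ok["rate"].min())
    out["max_state_rate_2020"] = float(ok["rate"].max())
    top8 = ok["deaths"].nlargest(8).sum()
    out["top8_state_share_pct_2020"] = top8 / national["deaths"] * 100.0

    summary = load_national_summary().set_index("year")
    r2010 = summary.loc[2010]
    r2020 = summary.loc[2020]
    out["national_rate_pct_change_2010_2020"] = percent_change(
        r2010["rate"], r2020["rate"]
    )
    lo, hi = percent_change_ci(
        (r2010["rate"], r2010["rate_lo"], r2010["rate_hi"]),
        (r2020["rate"], r2020["rate_lo"], r2020["rate_hi"]),
    )
    out["national_rate_pct_change_ci_lo"] = lo
    out["national_rate_pct_change_ci_hi"] = hi
    out["national_rate_2000"] = float(summary.loc[2000, "rate"])
    return out
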