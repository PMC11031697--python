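"""CSV readers and report writers for the three input schemas.

Input schemas (RFC-4180 CSV, UTF-8, one header row):

* admissions: state, year, sex, age_group, race_ethnicity,
  drug1..drug3, route1..route3 (route vocabulary "injection" / "other" /
  empty for missing)
* deaths: state, year, sex, age_years, race_ethnicity, ucod, tcodes
  (semicolon-separated ICD-10 T-codes, dotted or undotted)
* population: state, year, sex, age_group, race_ethnicity, population

Readers validate row-by-row; malformed rows are dropped and collected
in a validation report (``df.attrs["validation"]``) with their line
numbers.  A header that does not match the schema is a hard error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import AgeGroup, RaceEthnicity, Sex, YEAR_MAX, YEAR_MIN

logger = logging.getLogger(__name__)

_SEX = {s.value for s in Sex}
_AGE = {a.value for a in AgeGroup}
_RACE = {r.value for r in RaceEthnicity}

ADMISSION_COLS = [
    "state", "year", "sex", "age_group", "race_ethnicity",
    "drug1", "drug2", "drug3", "route1", "route2", "route3",
]
DEATH_COLS = ["state", "year", "sex", "age_years", "race_ethnicity", "ucod", "tcodes"]
POPULATION_COLS = ["state", "year", "sex", "age_group", "race_ethnicity", "population"]

_ROUTES = {"injection", "other", ""}


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")


def _common_row_errors(row) -> list[str]:
    errs = []
    state = str(row.state)
    if not (len(state) == 2 and state.isalpha() and state.isupper()):
        errs.append(f"bad state code {state!r}")
    try:
        year = int(row.year)
        if not YEAR_MIN <= year <= YEAR_MAX:
            errs.append(f"year {year} outside [{YEAR_MIN}, {YEAR_MAX}]")
    except (TypeError, ValueError):
        errs.append(f"bad year {row.year!r}")
    if str(row.sex) not in _SEX:
        errs.append(f"bad sex {row.sex!r}")
    if str(row.race_ethnicity) not in _RACE:
        errs.append(f"bad race_ethnicity {row.race_ethnicity!r}")
    return errs


def _validated(df: pd.DataFrame, row_errors: dict[int, list[str]], path) -> pd.DataFrame:
    if row_errors:
        for idx, errs in list(row_errors.items())[:10]:
            # +2: header line and 1-based numbering
            logger.warning("%s line %d rejected: %s", path, idx + 2, "; ".join(errs))
        logger.warning("%s: %d rows rejected", path, len(row_errors))
    out = df.drop(index=list(row_errors)).reset_index(drop=True)
    out.attrs["validation"] = {
        "n_read": len(df),
        "n_valid": len(out),
        "rejected_lines": {idx + 2: errs for idx, errs in row_errors.items()},
    }
    if len(out) == 0:
        logger.warning("%s: no valid rows", path)
    return out


def read_admissions(path) -> pd.DataFrame:
    """Read and validate the wide admission CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, ADMISSION_COLS, path)
    errors: dict[int, list[str]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        errs = _common_row_errors(row)
        if str(row.age_group) not in _AGE:
            errs.append(f"bad age_group {row.age_group!r}")
        for i in (1, 2, 3):
            route = str(getattr(row, f"route{i}"))
            if route not in _ROUTES and route != "missing":
                errs.append(f"bad route{i} {route!r}")
        if not any(str(getattr(row, f"drug{i}")).strip() for i in (1, 2, 3)):
            errs.append("no substance reported")
        if errs:
            errors[idx] = errs
    df = _validated(df, errors, path)
    df["year"] = df["year"].astype(int)
    return df


def read_deaths(path) -> pd.DataFrame:
    """Read and validate the death CSV; tcodes become tuples of strings."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, DEATH_COLS, path)
    errors: dict[int, list[str]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        errs = _common_row_errors(row)
        try:
            age = int(row.age_years)
            if not 0 <= age <= 130:
                errs.append(f"implausible age {age}")
        except (TypeError, ValueError):
            errs.append(f"bad age_years {row.age_years!r}")
        if not str(row.ucod).strip():
            errs.append("empty underlying cause")
        if errs:
            errors[idx] = errs
    df = _validated(df, errors, path)
    df["year"] = df["year"].astype(int)
    df["age_years"] = df["age_years"].astype(int)
    df["tcodes"] = [
        tuple(t for t in str(ts).split(";") if t.strip()) for ts in df["tcodes"]
    ]
    return df


def read_population(path) -> pd.DataFrame:
    """Read and validate the population-denominator CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, POPULATION_COLS, path)
    errors: dict[int, list[str]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        errs = _common_row_errors(row)
        if str(row.age_group) not in _AGE:
            errs.append(f"bad age_group {row.age_group!r}")
        try:
            if float(row.population) <= 0:
                errs.append(f"non-positive population {row.population!r}")
        except (TypeError, ValueError):
            errs.append(f"bad population {row.population!r}")
        if errs:
            errors[idx] = errs
    df = _validated(df, errors, path)
    df["year"] = df["year"].astype(int)
    df["population"] = df["population"].astype(float)
    return df


def write_deaths(deaths: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_deaths` (tcodes re-joined with ';')."""
    out = deaths.copy()
    out["tcodes"] = [";".join(t) for t in out["tcodes"]]
    out[DEATH_COLS].to_csv(path, index=False)


# --------------------------------------------------------------------------
# Report writers
# --------------------------------------------------------------------------

SUPPRESSED = "Suppressed"
NOT_AVAILABLE = "—"


def _fmt_deaths(point, lo, hi) -> str:
    return f"{point:.0f} ({lo:.0f}-{hi:.0f})"


def _fmt_pct(point, lo, hi) -> str:
    return f"{point:.1f} ({lo:.1f}-{hi:.1f})"


def _fmt_rate(point, lo, hi) -> str:
    return f"{point:.2f} ({lo:.2f}-{hi:.2f})"


def format_annual_table(estimates: pd.DataFrame, year: int) -> pd.DataFrame:
    """One-year state table: deaths, percent, and rate with 95% CIs.

    Suppressed state-years print "Suppressed" in all three result
    columns; states with no treatment data print an em-dash.  Deaths are
    rounded to integers, percentages to 1 decimal, rates to 2 decimals.
    """
    sub = estimates[estimates["year"] == year].sort_values("state")
    rows = []
    for r in sub.itertuples(index=False):
        if r.suppression_reason == "no_teds_data":
            deaths = pct = rate = NOT_AVAILABLE
        elif r.suppressed:
            deaths = pct = rate = SUPPRESSED
        else:
            deaths = _fmt_deaths(r.deaths_point, r.deaths_lo, r.deaths_hi)
            pct = _fmt_pct(r.pct_of_overdoses, r.pct_lo, r.pct_hi)
            rate = _fmt_rate(r.rate, r.rate_lo, r.rate_hi)
        rows.append(
            {
                "state": r.state,
                "population": round(r.population),
                "overdose_deaths": round(r.n_overdose),
                "injection_deaths_95ci": deaths,
                "pct_of_overdose_deaths_95ci": pct,
                "rate_per_100000_95ci": rate,
            }
        )
    return pd.DataFrame(rows)


def format_two_year_table(
    estimates: pd.DataFrame, year_a: int, year_b: int
) -> pd.DataFrame:
    """Two-year comparison table (counts and percentages only)."""
    parts = []
    for year in (year_a, year_b):
        t = format_annual_table(estimates, year)
        t = t.rename(
            columns={
                "overdose_deaths": f"overdose_deaths_{year}",
                "injection_deaths_95ci": f"injection_deaths_95ci_{year}",
                "pct_of_overdose_deaths_95ci": f"pct_95ci_{year}",
            }
        ).drop(columns=["population", "rate_per_100000_95ci"])
        parts.append(t.set_index("state"))
    return parts[0].join(parts[1], how="outer").reset_index()


def write_reports(
    state_estimates: pd.DataFrame,
    national: pd.DataFrame,
    outdir,
    years: tuple[int, int] | None = None,
    trends: pd.DataFrame | None = None,
    probabilities: pd.DataFrame | None = None,
    category_pcts: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write the full report bundle to ``outdir``; returns paths written.

    Produces per-year state tables (with the national row appended), a
    two-year comparison table, a long-format all-years file of
    unrounded estimates, and — when supplied — trend, probability
    (admission counts and percent injecting per state-year-drug), and
    death-category-share tables, plus a machine-readable run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    combined = pd.concat([state_estimates, national], ignore_index=True)
    all_years = sorted(state_estimates["year"].unique())
    for year in all_years:
        p = outdir / f"estimates_{year}.csv"
        format_annual_table(combined, year).to_csv(p, index=False)
        written[f"estimates_{year}"] = p

    if years is None and len(all_years) >= 2:
        years = (all_years[0], all_years[-1])
    if years is not None:
        p = outdir / f"estimates_{years[0]}_vs_{years[1]}.csv"
        format_two_year_table(combined, *years).to_csv(p, index=False)
        written["two_year"] = p

    p = outdir / "estimates_long.csv"
    combined.to_csv(p, index=False)
    written["long"] = p

    if trends is not None:
        p = outdir / "trends.csv"
        trends.to_csv(p, index=False)
        written["trends"] = p
    if probabilities is not None:
        p = outdir / "injection_probabilities.csv"
        probabilities.to_csv(p, index=False)
        written["probabilities"] = p
    if category_pcts is not None:
        p = outdir / "death_category_shares.csv"
        category_pcts.to_csv(p, index=False)
        written["category_shares"] = p

    if manifest is not None:
        p = outdir / "run_manifest.json"
        payload = dict(manifest)
        payload["versions"] = {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        p.write_text(json.dumps(payload, indent=2, default=_jsonify))
        written["manifest"] = p
    return written


def _jsonify(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
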