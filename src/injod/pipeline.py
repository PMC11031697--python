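"""End-to-end estimation pipeline: admissions + deaths + population in,
state and national injection-involved overdose estimates out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import (
    DrugType,
    filter_overdose_deaths,
    normalize_admissions_table,
)
from .death_allocation import category_percentages, tabulate_deaths
from .estimation import (
    SuppressionRules,
    apply_suppression,
    attach_population,
    estimate_injection_deaths,
    national_aggregate,
)
from .injection_probability import (
    ProbabilityLookup,
    missingness_summary,
    overall_injection_ranking,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; defaults follow the published procedure."""

    alpha: float = 0.05
    ci_mode: str = "endpoint"  # or "mc"
    n_mc: int = 2000
    suppression: SuppressionRules = field(default_factory=SuppressionRules)
    #: "national_year": rank drugs by national injection share per year;
    #: "national_pooled": one ranking pooled over all years.
    ranking_mode: str = "national_year"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha outside (0,1): {self.alpha}")
        if self.ci_mode not in ("endpoint", "mc"):
            raise ValueError(f"unknown ci_mode {self.ci_mode!r}")
        if self.ranking_mode not in ("national_year", "national_pooled"):
            raise ValueError(f"unknown ranking_mode {self.ranking_mode!r}")


@dataclass
class PipelineResult:
    admissions_long: pd.DataFrame
    probabilities: ProbabilityLookup
    missingness: pd.DataFrame
    ranking_by_year: Mapping[int, Sequence[DrugType]]
    allocated: pd.DataFrame
    category_shares: pd.DataFrame
    state_estimates: pd.DataFrame
    national: pd.DataFrame


def run_pipeline(
    admissions_wide: pd.DataFrame,
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full indirect-estimation procedure.

    Steps: normalize admissions to drug-of-interest reports; estimate
    stratified injection probabilities with exact CIs; rank drugs by
    national injection share (polydrug rule); filter deaths to adult
    overdoses, categorize and redistribute T50.9-only deaths; multiply
    probabilities into allocated counts and collapse to state-year
    estimates with rates; apply suppression; aggregate nationally over
    reporting states.
    """
    long = normalize_admissions_table(admissions_wide)
    logger.info("normalized %d admissions to %d drug reports",
                len(admissions_wide), len(long))
    lookup = ProbabilityLookup(long, alpha=config.alpha)
    missing = missingness_summary(long)

    od = filter_overdose_deaths(deaths)
    logger.info("%d of %d deaths are adult overdose deaths", len(od), len(deaths))
    years = sorted(set(od["year"]))
    if config.ranking_mode == "national_pooled":
        pooled = overall_injection_ranking(long, year=None)
        ranking = {y: pooled for y in years}
    else:
        ranking = {y: overall_injection_ranking(long, year=y) for y in years}

    allocated = tabulate_deaths(od, ranking)
    shares = category_percentages(allocated)

    rng = np.random.default_rng(config.seed)
    estimates = estimate_injection_deaths(
        allocated, lookup, ci_mode=config.ci_mode, n_mc=config.n_mc, rng=rng
    )
    estimates = attach_population(estimates, population)
    estimates = apply_suppression(estimates, missing, config.suppression)

    missing_prob_states = set(estimates.loc[
        estimates["suppression_reason"] == "no_teds_data", "state"
    ])
    if missing_prob_states:
        logger.info(
            "states with deaths but no treatment data: %s",
            ", ".join(sorted(missing_prob_states)),
        )

    national = national_aggregate(estimates, population)
    return PipelineResult(
        admissions_long=long,
        probabilities=lookup,
        missingness=missing,
        ranking_by_year=ranking,
        allocated=allocated,
        category_shares=shares,
        state_estimates=estimates,
        national=national,
    )


def probability_report(result: PipelineResult) -> pd.DataFrame:
    """State x year x drug admission counts and percent injecting.

    The per-drug analogue of the published supplementary treatment
    table: route-known admission counts and the percent reporting
    injection, pooled over strata.
    """
    t = result.probabilities.pooled_table("state_year_drug").copy()
    t["pct_injection"] = t["p_hat"] * 100.0
    return t[
        ["state", "year", "drug", "n_route_known", "n_injection", "pct_injection"]
    ]
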