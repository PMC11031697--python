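"""Synthetic admissions, deaths, and population files with known truth.

The generator emulates the structure of the two surveillance systems the
estimator links: admission records carry up to three substances with a
usual route of administration (route missing at a configurable rate),
and death records carry an overdose underlying cause plus
multiple-cause T-codes, with configurable polydrug and T50.9-only
("unspecified") fractions.  Every death also carries a latent
injected/not-injected flag drawn from the true injection probability of
its category, so the pipeline's estimates can be compared to a known
ground truth.

Defaults describe a 2020-era, heroin/synthetic-opioid-dominant drug
landscape at desk scale; see the package methods note for rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .coding import (
    CANONICAL_DRUG_ORDER,
    DEATH_CATEGORIES,
    TREATMENT_DRUGS,
    AgeGroup,
    DrugType,
    RaceEthnicity,
    Sex,
    all_strata,
)

#: One representative T-code per specific category (plus one OTHER_T code).
CATEGORY_TCODE: dict[DrugType, str] = {
    DrugType.HEROIN_SYNTH_OPIOID: "T40.1",
    DrugType.NAT_SEMI_OPIOID_METHADONE: "T40.2",
    DrugType.COCAINE: "T40.5",
    DrugType.PSYCHOSTIMULANT: "T43.6",
    DrugType.SEDATIVE: "T42.4",
    DrugType.OTHER_T: "T39.1",
}

OVERDOSE_UCODS = (
    ["X4" + str(i) for i in range(5)]
    + ["X6" + str(i) for i in range(5)]
    + ["X85"]
    + ["Y1" + str(i) for i in range(5)]
)

#: Raw substance names emitted for each drug group, to exercise the
#: sub-substance mapping (crack -> cocaine etc.).
_GROUP_SUBSTANCES: dict[DrugType, tuple[str, ...]] = {
    DrugType.HEROIN_SYNTH_OPIOID: ("heroin", "fentanyl"),
    DrugType.NAT_SEMI_OPIOID_METHADONE: ("other_opiate", "methadone"),
    DrugType.COCAINE: ("cocaine", "crack"),
    DrugType.PSYCHOSTIMULANT: ("methamphetamine", "amphetamine"),
    DrugType.SEDATIVE: ("benzodiazepine", "barbiturate"),
}


def _default_strata_weights() -> dict[tuple[str, str, str], float]:
    sex_w = {Sex.MALE: 0.62, Sex.FEMALE: 0.38}
    age_w = {AgeGroup.A18_39: 0.55, AgeGroup.A40_PLUS: 0.45}
    race_w = {
        RaceEthnicity.HISPANIC: 0.14,
        RaceEthnicity.NH_BLACK: 0.14,
        RaceEthnicity.NH_WHITE: 0.62,
        RaceEthnicity.NH_OTHER: 0.10,
    }
    return {
        s.as_tuple(): sex_w[s.sex] * age_w[s.age_group] * race_w[s.race_ethnicity]
        for s in all_strata()
    }


#: Baseline probability of injection among treatment admissions, by drug.
_DEFAULT_BASE_INJECTION = {
    DrugType.HEROIN_SYNTH_OPIOID: 0.60,
    DrugType.NAT_SEMI_OPIOID_METHADONE: 0.18,
    DrugType.COCAINE: 0.12,
    DrugType.PSYCHOSTIMULANT: 0.30,
    DrugType.SEDATIVE: 0.04,
}

#: Death-category mixture, 2020-like (heroin/synthetic-opioid dominant).
_DEFAULT_DEATH_MIXTURE = {
    DrugType.HEROIN_SYNTH_OPIOID: 0.45,
    DrugType.NAT_SEMI_OPIOID_METHADONE: 0.15,
    DrugType.COCAINE: 0.12,
    DrugType.PSYCHOSTIMULANT: 0.15,
    DrugType.SEDATIVE: 0.05,
    DrugType.OTHER_T: 0.08,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic surveillance dataset."""

    states: tuple[str, ...] = ("AL", "CA", "FL", "NY", "OH", "TX")
    year_start: int = 2010
    year_end: int = 2020
    state_population: Mapping[str, int] = field(
        default_factory=lambda: {
            "AL": 3_800_000,
            "CA": 30_000_000,
            "FL": 17_000_000,
            "NY": 15_000_000,
            "OH": 9_000_000,
            "TX": 22_000_000,
        }
    )
    strata_weights: Mapping[tuple[str, str, str], float] = field(
        default_factory=_default_strata_weights
    )
    base_injection_probs: Mapping[DrugType, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_INJECTION)
    )
    #: additive shift applied to the younger age band (clipped to [0.01, 0.99])
    young_injection_shift: float = 0.06
    death_mixture: Mapping[DrugType, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEATH_MIXTURE)
    )
    #: adult overdose deaths per 100,000 at year_start and year_end
    #: (linear in between); 2020-era national level is ~35.
    death_rate_start: float = 12.0
    death_rate_end: float = 35.0
    admissions_per_state_year: int = 5_000
    polydrug_prob: float = 0.40
    unspecified_fraction: float = 0.08
    route_missing_fraction: float = 0.008
    #: "matched" draws each latent injection flag from the category the
    #: estimator will assign; "misspecified" draws from the least-injected
    #: listed category, to quantify the polydrug overestimation.
    latent_mode: str = "matched"
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.year_end < self.year_start:
            errors.append("year_end before year_start")
        for name in ("polydrug_prob", "unspecified_fraction", "route_missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errors.append(f"{name}={v} outside [0, 1]")
        for d, p in self.base_injection_probs.items():
            if not 0 <= p <= 1:
                errors.append(f"injection prob for {d}: {p} outside [0, 1]")
        if abs(sum(self.death_mixture.values()) - 1.0) > 1e-9:
            errors.append("death_mixture must sum to 1")
        if self.admissions_per_state_year < 0:
            errors.append("admissions_per_state_year must be >= 0")
        if any(w < 0 for w in self.strata_weights.values()):
            errors.append("strata weights must be >= 0")
        missing_pop = [s for s in self.states if s not in self.state_population]
        if missing_pop:
            errors.append(f"state_population missing for {missing_pop}")
        if self.latent_mode not in ("matched", "misspecified"):
            errors.append(f"unknown latent_mode {self.latent_mode!r}")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def true_injection_prob(self, drug: DrugType, age_group: str) -> float:
        p = self.base_injection_probs[drug]
        if age_group == AgeGroup.A18_39.value:
            p += self.young_injection_shift
        return float(np.clip(p, 0.01, 0.99))

    def death_rate(self, year: int) -> float:
        if self.year_end == self.year_start:
            return self.death_rate_end
        frac = (year - self.year_start) / (self.year_end - self.year_start)
        return self.death_rate_start + frac * (
            self.death_rate_end - self.death_rate_start
        )


def true_probability_table(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth injection probability per (drug, stratum)."""
    rows = []
    for s in all_strata():
        sex, age, race = s.as_tuple()
        for drug in TREATMENT_DRUGS:
            rows.append(
                {
                    "drug": drug.value,
                    "sex": sex,
                    "age_group": age,
                    "race_ethnicity": race,
                    "p_true": config.true_injection_prob(drug, age),
                }
            )
    return pd.DataFrame(rows)


def _draw_strata(config: SimulationConfig, n: int, rng: np.random.Generator):
    strata = list(config.strata_weights)
    w = np.array([config.strata_weights[s] for s in strata], dtype=float)
    w = w / w.sum()
    idx = rng.choice(len(strata), size=n, p=w)
    return np.array(strata, dtype=object)[idx]


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic population denominators per state-year-stratum."""
    w_total = sum(config.strata_weights.values())
    rows = []
    for state in config.states:
        pop = config.state_population[state]
        for year in config.years:
            for (sex, age, race), w in config.strata_weights.items():
                rows.append(
                    {
                        "state": state,
                        "year": year,
                        "sex": sex,
                        "age_group": age,
                        "race_ethnicity": race,
                        "population": pop * w / w_total,
                    }
                )
    return pd.DataFrame(rows)


def generate_admissions(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Wide-format admission records (drug1..3 / route1..3 columns).

    For each record the stratum is drawn from the strata weights, 1-3
    distinct drug groups from the death-mixture prevalences (restricted
    to the five treatment drugs), the route is injection with the
    stratum's true probability, and the route is then masked to missing
    with the configured missingness fraction.
    """
    rng = rng or np.random.default_rng(config.seed)
    drugs = list(TREATMENT_DRUGS)
    prev = np.array([config.death_mixture[d] for d in drugs], dtype=float)
    prev = prev / prev.sum()
    n_drug_probs = [0.62, 0.30, 0.08]  # 1, 2, or 3 substances per admission

    records = []
    for state in config.states:
        for year in config.years:
            n = config.admissions_per_state_year
            strata = _draw_strata(config, n, rng)
            n_drugs = rng.choice([1, 2, 3], size=n, p=n_drug_probs)
            for i in range(n):
                sex, age, race = strata[i]
                k = n_drugs[i]
                chosen = rng.choice(len(drugs), size=k, replace=False, p=prev)
                row = {
                    "state": state,
                    "year": year,
                    "sex": sex,
                    "age_group": age,
                    "race_ethnicity": race,
                }
                for slot in range(3):
                    if slot < k:
                        drug = drugs[chosen[slot]]
                        names = _GROUP_SUBSTANCES[drug]
                        substance = names[int(rng.integers(len(names)))]
                        p = config.true_injection_prob(drug, age)
                        route = "injection" if rng.random() < p else "other"
                        if rng.random() < config.route_missing_fraction:
                            route = ""
                        row[f"drug{slot + 1}"] = substance
                        row[f"route{slot + 1}"] = route
                    else:
                        row[f"drug{slot + 1}"] = ""
                        row[f"route{slot + 1}"] = ""
                records.append(row)
    return pd.DataFrame(records)


def generate_deaths(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Death records plus per-death latent ground truth.

    Returns ``(deaths, truth)``: deaths in the flat schema (state,
    year, sex, age_years, race_ethnicity, ucod, tcodes as a tuple of
    code strings — written to CSV semicolon-joined) and truth with
    one row per death (death_id, true category, latent injected flag).
    The number of deaths per state-year is Poisson with mean
    rate x population / 100,000.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    categories = list(DEATH_CATEGORIES)
    mix = np.array([config.death_mixture[c] for c in categories], dtype=float)
    mix = mix / mix.sum()
    # ranking by true national injection probability (polydrug primary rule)
    canon = {d: i for i, d in enumerate(CANONICAL_DRUG_ORDER)}
    true_rank = {
        d: i
        for i, d in enumerate(
            sorted(
                TREATMENT_DRUGS,
                key=lambda d: (-config.base_injection_probs[d], canon[d]),
            )
        )
    }

    death_rows, truth_rows = [], []
    death_id = 0
    for state in config.states:
        pop = config.state_population[state]
        for year in config.years:
            mean = config.death_rate(year) * pop / 100_000.0
            n = int(rng.poisson(mean))
            strata = _draw_strata(config, n, rng)
            cat_idx = rng.choice(len(categories), size=n, p=mix)
            for i in range(n):
                sex, age_group, race = strata[i]
                category = categories[cat_idx[i]]
                listed = [category]
                if (
                    category in true_rank
                    and rng.random() < config.polydrug_prob
                ):
                    others = [d for d in TREATMENT_DRUGS if d != category]
                    listed.append(others[int(rng.integers(len(others)))])
                unspecified = rng.random() < config.unspecified_fraction
                tcodes = (
                    ["T50.9"]
                    if unspecified
                    else [CATEGORY_TCODE[c] for c in listed]
                )
                specific = [c for c in listed if c in true_rank]
                if not specific:
                    latent_cat = None  # OTHER_T: estimator assigns p = 0
                elif config.latent_mode == "matched":
                    latent_cat = min(specific, key=true_rank.__getitem__)
                else:
                    latent_cat = max(specific, key=true_rank.__getitem__)
                if latent_cat is None:
                    injected = 0
                else:
                    p = config.true_injection_prob(latent_cat, age_group)
                    injected = int(rng.random() < p)
                age = int(
                    rng.integers(18, 40)
                    if age_group == AgeGroup.A18_39.value
                    else rng.integers(40, 81)
                )
                death_rows.append(
                    {
                        "state": state,
                        "year": year,
                        "sex": sex,
                        "age_years": age,
                        "race_ethnicity": race,
                        "ucod": OVERDOSE_UCODS[int(rng.integers(len(OVERDOSE_UCODS)))],
                        "tcodes": tuple(tcodes),
                    }
                )
                truth_rows.append(
                    {
                        "death_id": death_id,
                        "state": state,
                        "year": year,
                        "true_category": (
                            latent_cat.value if latent_cat else DrugType.OTHER_T.value
                        ),
                        "injected": injected,
                    }
                )
                death_id += 1
    return pd.DataFrame(death_rows), pd.DataFrame(truth_rows)


def generate_all(
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Admissions, deaths, population, and truth from one seed."""
    rng = np.random.default_rng(config.seed)
    admissions = generate_admissions(config, rng)
    deaths, truth = generate_deaths(config, rng)
    population = generate_population(config)
    return {
        "admissions": admissions,
        "deaths": deaths,
        "population": population,
        "truth": truth,
    }
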