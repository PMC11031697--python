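"""Code lists, record-level classification, and eligibility filters.

Overdose deaths are identified from the underlying cause of death
(ICD-10 X40-X44, X60-X64, X85, Y10-Y14, adults only).  The substances
involved come from the multiple-cause T-codes, grouped into five
specific drug categories that mirror the treatment-admission drug
groups, plus a residual OTHER_T bucket (any other drug-poisoning code
in T36-T59.0) and UNSPECIFIED for deaths whose only T-code is T50.9
("other and unspecified drugs").

Treatment admissions report up to three substances with a usual route
of administration each; sub-substances (crack, methamphetamine,
benzodiazepines, ...) are collapsed onto the same five drug groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class AgeGroup(str, Enum):
    """Adult age bands; the cut is closed-open at 40 (18-39 vs >=40)."""

    A18_39 = "18-39"
    A40_PLUS = "40+"


class RaceEthnicity(str, Enum):
    HISPANIC = "Hispanic"
    NH_BLACK = "NH-Black"
    NH_WHITE = "NH-White"
    NH_OTHER = "NH-other"


class DrugType(str, Enum):
    """Five treatment drug groups, plus the two death-only categories."""

    HEROIN_SYNTH_OPIOID = "heroin_synth_opioid"
    NAT_SEMI_OPIOID_METHADONE = "nat_semi_opioid_methadone"
    COCAINE = "cocaine"
    PSYCHOSTIMULANT = "psychostimulant"
    SEDATIVE = "sedative"
    # death-only categories
    OTHER_T = "other_t"
    UNSPECIFIED = "unspecified"


#: The five drug types observable in both treatment and death data.
TREATMENT_DRUGS: tuple[DrugType, ...] = (
    DrugType.HEROIN_SYNTH_OPIOID,
    DrugType.NAT_SEMI_OPIOID_METHADONE,
    DrugType.COCAINE,
    DrugType.PSYCHOSTIMULANT,
    DrugType.SEDATIVE,
)

#: The six categories a death can be allocated to after redistribution.
DEATH_CATEGORIES: tuple[DrugType, ...] = TREATMENT_DRUGS + (DrugType.OTHER_T,)

#: Canonical drug order used to break ties in the injection ranking.
CANONICAL_DRUG_ORDER: tuple[DrugType, ...] = (
    DrugType.HEROIN_SYNTH_OPIOID,
    DrugType.NAT_SEMI_OPIOID_METHADONE,
    DrugType.PSYCHOSTIMULANT,
    DrugType.COCAINE,
    DrugType.SEDATIVE,
)

STRATUM_COLS = ("sex", "age_group", "race_ethnicity")

ADULT_AGE = 18
AGE_CUT = 40  # 18-39 vs >=40

YEAR_MIN, YEAR_MAX = 2000, 2020


@dataclass(frozen=True)
class DemographicStratum:
    """One of the 16 analytic strata (sex x age group x race/ethnicity)."""

    sex: Sex
    age_group: AgeGroup
    race_ethnicity: RaceEthnicity

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.sex.value, self.age_group.value, self.race_ethnicity.value)


def all_strata() -> list[DemographicStratum]:
    """Enumerate the 16 demographic strata in a fixed order."""
    return [
        DemographicStratum(s, a, r)
        for s, a, r in product(Sex, AgeGroup, RaceEthnicity)
    ]


def age_group_of(age_years: int) -> AgeGroup:
    if age_years < ADULT_AGE:
        raise ValueError(f"age {age_years} is below the adult cutoff ({ADULT_AGE})")
    return AgeGroup.A18_39 if age_years < AGE_CUT else AgeGroup.A40_PLUS


# --------------------------------------------------------------------------
# ICD-10 handling
# --------------------------------------------------------------------------

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})\.?(\d{0,2})$")


def canonical_icd10(code: str) -> str:
    """Normalize an ICD-10 code to its dotted canonical form.

    Accepts both dotted ("T40.1") and undotted ("T401") dialects, as
    vital-statistics files use the undotted form while user-prepared
    CSVs are usually dotted.

    Raises ValueError on anything that does not parse as an ICD-10 code.
    """
    m = _ICD10_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(f"unparseable ICD-10 code: {code!r}")
    letter, major, minor = m.groups()
    return f"{letter}{major}.{minor}" if minor else f"{letter}{major}"


def _icd10_value(canonical: str) -> tuple[str, float]:
    """(letter, numeric value) for range comparisons; 'T40.1' -> ('T', 40.1)."""
    letter = canonical[0]
    return letter, float(canonical[1:])


#: Underlying-cause ranges defining a drug overdose death.
_OVERDOSE_UCOD_RANGES: tuple[tuple[str, float, float], ...] = (
    ("X", 40, 44),  # accidental poisoning
    ("X", 60, 64),  # intentional self-poisoning
    ("X", 85, 85),  # assault by drugs
    ("Y", 10, 14),  # undetermined intent
)


def is_overdose_ucod(underlying_cause: str) -> bool:
    """True iff the underlying cause is a drug-overdose ICD-10 code."""
    letter, value = _icd10_value(canonical_icd10(underlying_cause))
    major = int(value)  # sub-codes (e.g. X42.0) inherit the category
    return any(
        letter == lt and lo <= major <= hi for lt, lo, hi in _OVERDOSE_UCOD_RANGES
    )


#: Specific multiple-cause T-codes -> drug category.
TCODE_CATEGORIES: dict[str, DrugType] = {
    "T40.1": DrugType.HEROIN_SYNTH_OPIOID,
    "T40.4": DrugType.HEROIN_SYNTH_OPIOID,
    "T40.2": DrugType.NAT_SEMI_OPIOID_METHADONE,
    "T40.3": DrugType.NAT_SEMI_OPIOID_METHADONE,
    "T40.5": DrugType.COCAINE,
    "T43.6": DrugType.PSYCHOSTIMULANT,
    "T42.3": DrugType.SEDATIVE,
    "T42.4": DrugType.SEDATIVE,
}

UNSPECIFIED_TCODE = "T50.9"

_OTHER_T_LO, _OTHER_T_HI = 36.0, 59.0


def map_tcodes_to_categories(tcodes: Iterable[str]) -> frozenset[DrugType]:
    """Map a death record's T-codes to the drug categories they imply.

    Returns ``{UNSPECIFIED}`` iff the record lists no drug-poisoning
    T-code other than T50.9 (including an empty list).  A death listing
    a specific code alongside T50.9 is classified by its specific codes.
    Any other code within T36-T59.0 maps to OTHER_T; codes outside that
    range are not drug-poisoning codes and are ignored with a warning.
    """
    categories: set[DrugType] = set()
    saw_only_unspecified = True
    for raw in tcodes:
        code = canonical_icd10(raw)
        if code == UNSPECIFIED_TCODE:
            continue
        letter, value = _icd10_value(code)
        if letter != "T" or not (_OTHER_T_LO <= value <= _OTHER_T_HI):
            logger.warning("ignoring non-drug-poisoning code %s", code)
            continue
        saw_only_unspecified = False
        categories.add(TCODE_CATEGORIES.get(code, DrugType.OTHER_T))
    if saw_only_unspecified:
        return frozenset({DrugType.UNSPECIFIED})
    return frozenset(categories)


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DeathRecord:
    state: str
    year: int
    stratum: DemographicStratum
    underlying_cause: str
    tcodes: tuple[str, ...]
    age_years: int


class Route(str, Enum):
    INJECTION = "injection"
    OTHER = "other"
    MISSING = "missing"


#: Preference order when deduplicating routes for the same drug group.
_ROUTE_PRIORITY = {Route.INJECTION: 0, Route.OTHER: 1, Route.MISSING: 2}


@dataclass(frozen=True)
class AdmissionRecord:
    state: str
    year: int
    stratum: DemographicStratum
    substances: tuple[tuple[DrugType, Route], ...] = field(default_factory=tuple)


def is_overdose_death(record: DeathRecord) -> bool:
    """Adult drug-overdose death per underlying cause and age >= 18."""
    try:
        overdose = is_overdose_ucod(record.underlying_cause)
    except ValueError as exc:
        raise ValueError(
            f"death record ({record.state}, {record.year}): {exc}"
        ) from exc
    return overdose and record.age_years >= ADULT_AGE


#: Raw substance vocabulary -> treatment drug group.  Sub-substances
#: collapse onto the five groups; anything absent here (alcohol,
#: cannabis, ...) is not a drug of interest.
SUBSTANCE_GROUPS: dict[str, DrugType] = {
    "heroin": DrugType.HEROIN_SYNTH_OPIOID,
    "synthetic_opioid": DrugType.HEROIN_SYNTH_OPIOID,
    "fentanyl": DrugType.HEROIN_SYNTH_OPIOID,
    "natural_opioid": DrugType.NAT_SEMI_OPIOID_METHADONE,
    "semisynthetic_opioid": DrugType.NAT_SEMI_OPIOID_METHADONE,
    "other_opiate": DrugType.NAT_SEMI_OPIOID_METHADONE,
    "methadone": DrugType.NAT_SEMI_OPIOID_METHADONE,
    "cocaine": DrugType.COCAINE,
    "crack": DrugType.COCAINE,
    "methamphetamine": DrugType.PSYCHOSTIMULANT,
    "amphetamine": DrugType.PSYCHOSTIMULANT,
    "other_stimulant": DrugType.PSYCHOSTIMULANT,
    "benzodiazepine": DrugType.SEDATIVE,
    "tranquilizer": DrugType.SEDATIVE,
    "barbiturate": DrugType.SEDATIVE,
    "other_sedative": DrugType.SEDATIVE,
}

# canonical drug-group names are accepted verbatim as well
SUBSTANCE_GROUPS.update({d.value: d for d in TREATMENT_DRUGS})


def normalize_admissions_table(wide: "pd.DataFrame") -> "pd.DataFrame":
    """Long-format drug-of-interest reports from wide admission rows.

    Input columns: state, year, sex, age_group, race_ethnicity,
    drug1..drug3, route1..route3 (empty route = missing).  Output: one
    row per (admission, drug group) after sub-substance mapping and
    per-record deduplication, with a ``record_id`` tying reports back to
    their admission (needed to count distinct admissions).  Admissions
    with no drug of interest contribute no rows.
    """
    import pandas as pd  # local import keeps module import light

    slots = [(f"drug{i}", f"route{i}") for i in (1, 2, 3)]
    cache: dict[tuple, tuple[tuple[DrugType, Route], ...]] = {}
    rows = []
    for rid, row in enumerate(wide.itertuples(index=False)):
        raw = tuple(
            (str(getattr(row, d, "") or ""), str(getattr(row, r, "") or ""))
            for d, r in slots
        )
        if raw not in cache:
            cache[raw] = normalize_substances(raw)
        for drug, route in cache[raw]:
            rows.append(
                (
                    rid,
                    row.state,
                    int(row.year),
                    row.sex,
                    row.age_group,
                    row.race_ethnicity,
                    drug.value,
                    route.value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "state",
            "year",
            "sex",
            "age_group",
            "race_ethnicity",
            "drug",
            "route",
        ],
    )


def filter_overdose_deaths(deaths: "pd.DataFrame") -> "pd.DataFrame":
    """Keep adult drug-overdose deaths and attach the age band.

    Expects columns ucod and age_years; rows with an unparseable
    underlying cause raise with the offending row index in the message.
    """
    ucods = deaths["ucod"].astype(str)
    verdict = {}
    for code in ucods.unique():
        try:
            verdict[code] = is_overdose_ucod(code)
        except ValueError as exc:
            rows = deaths.index[ucods == code].tolist()[:5]
            raise ValueError(f"rows {rows}: {exc}") from exc
    keep = ucods.map(verdict) & (deaths["age_years"] >= ADULT_AGE)
    out = deaths[keep].copy()
    out["age_group"] = [
        age_group_of(a).value for a in out["age_years"].astype(int)
    ]
    return out


def normalize_substances(
    raw: Sequence[tuple[str, str]],
) -> tuple[tuple[DrugType, Route], ...]:
    """Collapse raw (substance, route) slots to deduplicated drug groups.

    Duplicate drug groups within one admission keep the most informative
    route: injection over other over missing.  Substances outside the
    five groups are dropped (the record itself is retained for
    total-admission counts).
    """
    best: dict[DrugType, Route] = {}
    for substance, route_str in raw:
        name = substance.strip().lower()
        if not name:
            continue
        drug = SUBSTANCE_GROUPS.get(name)
        if drug is None:
            continue
        route = Route(route_str) if route_str else Route.MISSING
        if drug not in best or _ROUTE_PRIORITY[route] < _ROUTE_PRIORITY[best[drug]]:
            best[drug] = route
    return tuple(sorted(best.items(), key=lambda kv: kv[0].value))
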