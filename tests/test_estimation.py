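"""Product estimation, rates, suppression, and national aggregation."""

import numpy as np
import pandas as pd
import pytest

from injod.estimation import (
    SuppressionRules,
    apply_suppression,
    attach_population,
    compute_rate,
    estimate_injection_deaths,
    national_aggregate,
)
from injod.injection_probability import ProbabilityLookup
from injod.pipeline import RunConfig, run_pipeline
from injod.synthetic_data import SimulationConfig, generate_all


def _long(rows):
    return pd.DataFrame(
        rows,
        columns=["record_id", "state", "year", "sex", "age_group",
                 "race_ethnicity", "drug", "route"],
    )


def _adm_cell(n_inj, n_other, sex="male", state="AL", drug="heroin_synth_opioid",
              rid0=0):
    routes = ["injection"] * n_inj + ["other"] * n_other
    return [(rid0 + i, state, 2020, sex, "18-39", "NH-White", drug, r)
            for i, r in enumerate(routes)]


def _alloc(rows):
    return pd.DataFrame(
        rows,
        columns=["state", "year", "sex", "age_group", "race_ethnicity",
                 "category", "count", "n_overdose", "n_unspecified_input"],
    )


class TestEstimate:
    def test_single_product(self):
        """p = 0.5 with 100 deaths -> 50 injection-involved."""
        lookup = ProbabilityLookup(_long(_adm_cell(10, 10)))
        alloc = _alloc([
            ("AL", 2020, "male", "18-39", "NH-White", "heroin_synth_opioid",
             100.0, 100.0, 0.0),
        ])
        out = estimate_injection_deaths(alloc, lookup)
        assert out["deaths_point"].iloc[0] == pytest.approx(50.0)
        assert out["pct_of_overdoses"].iloc[0] == pytest.approx(50.0)
        assert out["deaths_lo"].iloc[0] < 50.0 < out["deaths_hi"].iloc[0]

    def test_two_strata_hand_arithmetic(self):
        """(0.6 x 10) + (0.4 x 20) = 14."""
        rows = _adm_cell(6, 4, sex="male") + _adm_cell(4, 6, sex="female", rid0=50)
        lookup = ProbabilityLookup(_long(rows))
        alloc = _alloc([
            ("AL", 2020, "male", "18-39", "NH-White", "heroin_synth_opioid",
             10.0, 30.0, 0.0),
            ("AL", 2020, "female", "18-39", "NH-White", "heroin_synth_opioid",
             20.0, 30.0, 0.0),
        ])
        out = estimate_injection_deaths(alloc, lookup)
        assert out["deaths_point"].iloc[0] == pytest.approx(14.0)

    def test_other_t_contributes_zero(self):
        lookup = ProbabilityLookup(_long(_adm_cell(10, 0)))
        alloc = _alloc([
            ("AL", 2020, "male", "18-39", "NH-White", "other_t", 25.0, 25.0, 0.0),
        ])
        out = estimate_injection_deaths(alloc, lookup)
        assert out["deaths_point"].iloc[0] == 0.0
        assert out["n_overdose"].iloc[0] == 25.0

    def test_estimate_bounded_by_raw_deaths(self, small_result):
        est = small_result.state_estimates
        assert (est["deaths_point"] <= est["n_overdose"] + 1e-9).all()
        assert (est["deaths_point"] >= 0).all()
        ok = est[~est["suppressed"]]
        assert ok["pct_of_overdoses"].between(0, 100).all()

    def test_interval_orders(self, small_result):
        est = small_result.state_estimates
        assert (est["deaths_lo"] <= est["deaths_point"] + 1e-12).all()
        assert (est["deaths_point"] <= est["deaths_hi"] + 1e-12).all()

    def test_mc_mode_brackets_point(self):
        rows = _adm_cell(30, 20)
        lookup = ProbabilityLookup(_long(rows))
        alloc = _alloc([
            ("AL", 2020, "male", "18-39", "NH-White", "heroin_synth_opioid",
             100.0, 100.0, 0.0),
        ])
        out = estimate_injection_deaths(
            alloc, lookup, ci_mode="mc", rng=np.random.default_rng(5)
        )
        row = out.iloc[0]
        assert row["deaths_lo"] < row["deaths_point"] < row["deaths_hi"]


def test_ci_width_shrinks_with_admission_volume():
    """95% interval narrows as the admission denominator grows."""
    widths = []
    for n in (50, 500, 5000):
        cfg = SimulationConfig(
            states=("AL",), year_start=2020, year_end=2020,
            state_population={"AL": 2_000_000},
            admissions_per_state_year=n, seed=99,
        )
        data = generate_all(cfg)
        res = run_pipeline(
            data["admissions"], data["deaths"], data["population"],
            RunConfig(seed=99),
        )
        row = res.state_estimates.iloc[0]
        widths.append((row["deaths_hi"] - row["deaths_lo"]) / row["n_overdose"])
    assert widths[0] > widths[1] > widths[2]


class TestComputeRate:
    def test_published_alabama_arithmetic(self):
        assert compute_rate(456, 3_834_249) == pytest.approx(11.89, abs=0.005)

    def test_published_national_arithmetic(self):
        # reporting-state population: 256,662,010 minus the five
        # non-reporting states' 17,140,128
        assert compute_rate(38_253, 239_521_882) == pytest.approx(15.97, abs=0.005)

    def test_zero_deaths(self):
        assert compute_rate(0, 1_000_000) == 0.0

    def test_rejects_nonpositive_population(self):
        with pytest.raises(ValueError):
            compute_rate(10, 0)


def _est(state, n_adm, missing_frac):
    estimates = pd.DataFrame([{
        "state": state, "year": 2020, "n_overdose": 100.0,
        "deaths_point": 40.0, "deaths_lo": 30.0, "deaths_hi": 50.0,
    }])
    missing = pd.DataFrame([{
        "state": state, "year": 2020, "n_admissions": n_adm,
        "n_reporting_drug": n_adm, "n_missing_route": 0,
        "missing_fraction": missing_frac,
    }])
    return apply_suppression(estimates, missing, SuppressionRules())


class TestSuppression:
    def test_49_admissions_suppressed(self):
        out = _est("AL", 49, 0.0)
        assert out["suppressed"].iloc[0]
        assert out["suppression_reason"].iloc[0] == "admissions_lt_50"

    def test_50_admissions_kept(self):
        out = _est("AL", 50, 0.10)
        assert not out["suppressed"].iloc[0]

    def test_over_15pct_missing_suppressed(self):
        out = _est("AL", 1000, 0.16)
        assert out["suppression_reason"].iloc[0] == "missing_gt_15pct"

    def test_exactly_15pct_missing_kept(self):
        # the threshold is strict: suppress only when fraction > 0.15
        out = _est("AL", 1000, 0.15)
        assert not out["suppressed"].iloc[0]

    def test_15_1pct_missing_suppressed(self):
        out = _est("AL", 1000, 0.151)
        assert out["suppressed"].iloc[0]

    def test_state_without_treatment_data(self):
        estimates = pd.DataFrame([{
            "state": "ID", "year": 2020, "n_overdose": 100.0,
            "deaths_point": 0.0, "deaths_lo": 0.0, "deaths_hi": 0.0,
        }])
        missing = pd.DataFrame(
            columns=["state", "year", "n_admissions", "n_reporting_drug",
                     "n_missing_route", "missing_fraction"]
        )
        out = apply_suppression(estimates, missing)
        assert out["suppression_reason"].iloc[0] == "no_teds_data"


def _state_estimates():
    rows = []
    for state, reason in (("AL", "none"), ("CA", "admissions_lt_50"),
                          ("ID", "no_teds_data")):
        rows.append({
            "state": state, "year": 2020, "n_overdose": 100.0,
            "deaths_point": 40.0, "deaths_lo": 30.0, "deaths_hi": 50.0,
            "suppressed": reason != "none", "suppression_reason": reason,
        })
    return pd.DataFrame(rows)


def _population():
    rows = []
    for state in ("AL", "CA", "ID"):
        rows.append({"state": state, "year": 2020, "sex": "male",
                     "age_group": "18-39", "race_ethnicity": "NH-White",
                     "population": 1_000_000.0})
    return pd.DataFrame(rows)


class TestNationalAggregate:
    def test_suppressed_states_count_nonreporting_excluded(self):
        nat = national_aggregate(_state_estimates(), _population())
        row = nat.iloc[0]
        # AL + CA (suppressed) in the numerator; ID (no data) excluded
        assert row["deaths_point"] == pytest.approx(80.0)
        assert row["population"] == pytest.approx(2_000_000.0)
        assert row["n_overdose"] == pytest.approx(200.0)
        assert row["rate"] == pytest.approx(compute_rate(80.0, 2_000_000.0))

    def test_single_state_equals_national(self):
        est = _state_estimates().iloc[[0]]
        pop = _population().iloc[[0]]
        nat = national_aggregate(est, pop)
        assert nat["deaths_point"].iloc[0] == pytest.approx(40.0)
        assert nat["population"].iloc[0] == pytest.approx(1_000_000.0)

    def test_national_equals_sum_of_reporting_states(self, small_result):
        est = small_result.state_estimates
        nat = small_result.national
        for year, sub in est.groupby("year"):
            rep = sub[sub["suppression_reason"] != "no_teds_data"]
            nrow = nat[nat["year"] == year].iloc[0]
            assert nrow["deaths_point"] == pytest.approx(
                rep["deaths_point"].sum(), abs=1e-6
            )
            assert nrow["deaths_lo"] == pytest.approx(
                rep["deaths_lo"].sum(), abs=1e-6
            )


def test_attach_population_errors_on_missing_state():
    est = _state_estimates()
    pop = _population()[lambda d: d["state"] != "CA"]
    with pytest.raises(ValueError, match="CA"):
        attach_population(est, pop)
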