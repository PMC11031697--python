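import numpy as np
import pytest

from injod.pipeline import RunConfig, run_pipeline
from injod.synthetic_data import SimulationConfig, generate_all


@pytest.fixture(scope="session")
def small_sim():
    """Two states, two years, modest volume; fast enough for many tests."""
    cfg = SimulationConfig(
        states=("AL", "CA"),
        year_start=2019,
        year_end=2020,
        state_population={"AL": 2_000_000, "CA": 2_000_000},
        admissions_per_state_year=1_500,
        seed=42,
    )
    return cfg, generate_all(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim):
    cfg, data = small_sim
    return run_pipeline(
        data["admissions"], data["deaths"], data["population"], RunConfig(seed=42)
    )


def make_recovery_config(seed: int) -> SimulationConfig:
    """One-year, six-state dataset sized for ~50,000 overdose deaths,
    with admission volumes large enough to populate most probability
    cells directly."""
    pops = {
        "AL": 5_600_000,
        "CA": 44_300_000,
        "FL": 25_100_000,
        "NY": 22_100_000,
        "OH": 13_300_000,
        "TX": 32_500_000,
    }
    return SimulationConfig(
        states=tuple(pops),
        year_start=2020,
        year_end=2020,
        state_population=pops,
        admissions_per_state_year=20_000,
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Generated data plus pipeline result for the large recovery check."""
    cfg = make_recovery_config(seed=20200)
    data = generate_all(cfg)
    result = run_pipeline(
        data["admissions"], data["deaths"], data["population"],
        RunConfig(seed=20200),
    )
    return cfg, data, result


def latent_count_se(truth) -> float:
    """Monte-Carlo SE of the latent injection count, from the empirical
    injection fraction (sum of independent Bernoulli flags)."""
    p = truth["injected"].mean()
    return float(np.sqrt(len(truth) * p * (1.0 - p)))
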