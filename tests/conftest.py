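import numpy as np
import pytest

from nestedwell import (
    RateSet,
    StepSchedule,
    fit_all_steps,
    generate_probe_pair,
    langmuir_pair_fit,
    make_default_schedule,
)

# study-condition truth used by the recovery fixtures
TRUE = dict(K1=200.0, K2=0.16, kon1=1.6e-5, kon2=5e-2, sigma_inf=1000.0)
TRUE_KD_EFF = TRUE["K1"] * TRUE["K2"] / (1.0 + TRUE["K2"])  # 27.586 nM


@pytest.fixture(scope="session")
def nw_rates() -> RateSet:
    """Moderate-exchange nested-well rates used in the worked examples."""
    return RateSet(kon1=1.6e-5, koff1=3.2e-3, kon2=5e-3, koff2=8e-4)


@pytest.fixture(scope="session")
def single_well_rates() -> RateSet:
    return RateSet(kon1=1.6e-5, koff1=3.2e-3)


@pytest.fixture(scope="session")
def short_schedule() -> StepSchedule:
    return StepSchedule(step_times=(0.0, 1500.0, 3000.0),
                        concentrations=(2.0, 10.0, 50.0))


@pytest.fixture(scope="session")
def noiseless_pair():
    """Default-condition noiseless specific/nonspecific trace pair."""
    return generate_probe_pair(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_steps(noiseless_pair):
    sp, ns = noiseless_pair
    return fit_all_steps(sp), fit_all_steps(ns)


@pytest.fixture(scope="session")
def noiseless_isotherm(noiseless_steps):
    steps_sp, steps_ns = noiseless_steps
    return langmuir_pair_fit(steps_sp, steps_ns)


@pytest.fixture(scope="session")
def default_schedule() -> StepSchedule:
    return make_default_schedule()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
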