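import numpy as np
import pytest

from ehrcast import (
    BassParams,
    CohortSpec,
    Generation,
    GenerationsModel,
    forecast,
    load_table2,
    load_table2_insample,
    sequential_then_joint,
    simulate_panel,
)


@pytest.fixture(scope="session")
def table2_model():
    return load_table2()


@pytest.fixture(scope="session")
def insample_model():
    return load_table2_insample()


@pytest.fixture(scope="session")
def table2_curves(table2_model):
    return forecast(table2_model)


@pytest.fixture(scope="session")
def recovery_fit(insample_model):
    """The noise-free self-fit experiment: simulate a deterministic
    cohort 2006-2014 from the in-sample fixture and refit it."""
    spec = CohortSpec(model=insample_model, n_units=5200, mode="deterministic")
    _, panel = simulate_panel(spec)
    fit = sequential_then_joint(panel, insample_model, seed=1)
    return fit


def two_generation_toy():
    gens = (
        Generation(0, 100.0, 0.0, BassParams(0.1, 0.0)),
        Generation(1, 50.0, 0.0, BassParams(0.1, 0.0)),
    )
    return GenerationsModel(2000, 2050, gens)


@pytest.fixture
def two_gen_model():
    return two_generation_toy()
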