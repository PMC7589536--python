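import numpy as np
import pandas as pd
import pytest

from sceptic import core, synth


@pytest.fixture(scope="session")
def basis():
    return core.build_basis()


@pytest.fixture(scope="session")
def small_sim():
    """4 selective agents x 2 runs x 50 trials, with uncertainty tracking."""
    pop = synth.gen_population(synth.PopulationSpec(n_subjects=4, seed=11))
    return synth.simulate_experiment(pop, schedule=("IEV", "DEV"), seed=12)


@pytest.fixture(scope="session")
def cev_sim():
    """2 agents on a single unlearnable CEV run."""
    pop = synth.gen_population(synth.PopulationSpec(n_subjects=2, seed=21))
    return synth.simulate_experiment(pop, schedule=("CEV",), seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
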