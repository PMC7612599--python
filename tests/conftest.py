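import numpy as np
import pytest

from blrm2 import (
    DesignConfig,
    MethadoneDistribution,
    PriorHyperparameters,
    ReferenceDoses,
    SamplerSettings,
    ThetaVector,
    Scenario,
)


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture(scope="session")
def hyper():
    return PriorHyperparameters()


@pytest.fixture(scope="session")
def refs():
    return ReferenceDoses()


@pytest.fixture(scope="session")
def methadone_dist():
    return MethadoneDistribution()


@pytest.fixture(scope="session")
def fast_settings():
    # small but adequate chains for unit-level checks
    return SamplerSettings(n_walkers=30, n_steps=600, n_burn=200)


@pytest.fixture(scope="session")
def safe_scenario():
    """Synthetic stand-in for a safe logistic surface.

    Constructed from the definition alone: the highest baclofen dose is the
    target dose (true risk ~ 0.20) at a methadone dose as high as 120 mg,
    and the safety-check combination is clearly safe (risk ~ 0.06).
    """
    return Scenario(
        "logistic5",
        ThetaVector(alpha01=-4.2, alpha11=1.2, alpha02=-3.4, alpha12=0.6, eta=0.45),
        label="synthetic-safe",
    )


@pytest.fixture(scope="session")
def unsafe_scenario():
    """Synthetic stand-in for a highly toxic surface (all combinations)."""
    return Scenario(
        "logistic5",
        ThetaVector(alpha01=-0.8, alpha11=0.9, alpha02=-1.2, alpha12=0.5, eta=0.8),
        label="synthetic-unsafe",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
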