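import numpy as np
import pytest

from cpgset import (
    BetaMarginalSpec,
    CorrelationTarget,
    DiseaseModelSpec,
    MethylationMatrix,
    ScenarioSpec,
    calibrate_copula,
    sample_case_control,
)


@pytest.fixture(scope="session")
def small_null_scenario() -> ScenarioSpec:
    """Small null scenario: 6 CpGs, exchangeable r = 0.5, 60 + 60 samples."""
    marginals = [BetaMarginalSpec(0.5, 10.0)] * 6
    return ScenarioSpec(
        marginals,
        CorrelationTarget.exchangeable(0.5, 6),
        DiseaseModelSpec(),
        n_cases=60,
        n_controls=60,
        label="unit-null",
    )


@pytest.fixture(scope="session")
def small_dataset(small_null_scenario) -> tuple[MethylationMatrix, np.ndarray]:
    return sample_case_control(small_null_scenario, seed=20160603)


@pytest.fixture(scope="session")
def exchangeable_copula():
    """Calibrated copula: 4 identical marginals, exchangeable r = 0.6."""
    marginals = [BetaMarginalSpec(0.6, 10.0)] * 4
    return calibrate_copula(marginals, CorrelationTarget.exchangeable(0.6, 4))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
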