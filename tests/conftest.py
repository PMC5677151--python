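import numpy as np
import pytest

from demoscope.demography import PiecewiseDemography


@pytest.fixture
def const_pop() -> PiecewiseDemography:
    return PiecewiseDemography.single_population([(0, 10_000)], mutation_rate=1.25e-8)


@pytest.fixture
def bottleneck_pop() -> PiecewiseDemography:
    return PiecewiseDemography.single_population(
        [(0, 10_000), (1_000, 1_000)], mutation_rate=1.25e-8
    )


@pytest.fixture
def three_epoch_pop() -> PiecewiseDemography:
    return PiecewiseDemography.single_population(
        [(0, 20_000), (500, 2_000), (3_000, 8_000)], mutation_rate=1.25e-8
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
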