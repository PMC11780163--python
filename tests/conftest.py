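import numpy as np
import pytest

from multisense.synthetic import (
    ObserverSpec,
    StimulusDesign,
    build_stimulus_design,
    simulate_observer_responses,
)


@pytest.fixture(scope="session")
def study_design() -> StimulusDesign:
    """The study's 9-level, 90-pair comparison ladder."""
    return StimulusDesign()


@pytest.fixture(scope="session")
def unimodal_observer() -> ObserverSpec:
    """A probit observer with matched tactile and blurred-visual noise."""
    return ObserverSpec(
        conditions={"T": (0.24442, 0.15), "VB": (0.24442, 0.15)},
        integration_mode="optimal",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def simulate_condition(design, spec, condition, seed, n_reps=None):
    """Simulate one condition's trial list, optionally rescaling the design."""
    d = design if n_reps is None else StimulusDesign(n_reps=n_reps)
    pairs = build_stimulus_design(d, seed)
    return simulate_observer_responses(pairs, spec, condition, seed + 100_003)
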