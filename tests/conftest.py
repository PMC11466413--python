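import numpy as np
import pytest

from numbci import (
    Condition,
    ModelSpec,
    ObserverParams,
    SimulationState,
    av_conditions,
    simulate_trials,
    unisensory_conditions,
)


@pytest.fixture
def ma_scalar_spec():
    return ModelSpec("MA", "scalar")


@pytest.fixture
def midrange_params():
    """Mid-range observer: auditory more precise than visual, mild scalar
    variability, small lapse."""
    return ObserverParams(
        p_common=0.5,
        mu_p=2.5,
        sigma_p=1.5,
        sigma_a=0.4,
        sigma_v=1.0,
        dsigma_a=0.2,
        dsigma_v=0.5,
        lapse=0.05,
    )


@pytest.fixture
def all_conditions():
    return av_conditions() + unisensory_conditions()


@pytest.fixture
def small_trial_table(midrange_params, ma_scalar_spec, all_conditions):
    state = SimulationState(123, n_sim=1000)
    table = simulate_trials(all_conditions, midrange_params, ma_scalar_spec, state, 40)
    table["subject"] = "S1"
    return table


def sample_generating_params(spec: ModelSpec, rng: np.random.Generator) -> ObserverParams:
    """Plausible generating parameters for recovery harnesses."""
    kw = dict(
        mu_p=rng.uniform(2.0, 3.0),
        sigma_p=rng.uniform(1.0, 2.0),
        sigma_a=rng.uniform(0.3, 0.6),
        sigma_v=rng.uniform(0.8, 1.3),
        lapse=rng.uniform(0.0, 0.1),
    )
    if spec.variance_mode == "scalar":
        kw["dsigma_a"] = rng.uniform(0.1, 0.3)
        kw["dsigma_v"] = rng.uniform(0.3, 0.7)
    name = spec.causal_param_name
    if name == "p_common":
        kw["p_common"] = rng.uniform(0.3, 0.8)
    elif name == "k":
        kw["k"] = rng.uniform(0.5, 2.5)
    else:
        kw["eta"] = rng.uniform(0.2, 0.8)
    return ObserverParams(**kw)
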