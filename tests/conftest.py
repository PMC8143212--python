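import numpy as np
import pytest

from atgdyn import (
    MitophagyParams,
    ModelVariant,
    NonselectiveParams,
    TimeCourse,
    nonselective_curve,
)


@pytest.fixture
def nonselective_params() -> NonselectiveParams:
    return NonselectiveParams()


@pytest.fixture
def mitophagy_params() -> MitophagyParams:
    return MitophagyParams()


@pytest.fixture
def variant3() -> ModelVariant:
    return ModelVariant(3)


def make_pulse_datasets(
    params: NonselectiveParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    horizon: float = 600.0,
    dt: float = 10.0,
) -> dict[str, list[TimeCourse]]:
    """Synchronized mean traces for both conditions, simulated at ``params``."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon + 0.5 * dt, dt)
    out: dict[str, list[TimeCourse]] = {}
    for cond, wtm in [("starvation", False), ("starvation+wortmannin", True)]:
        a = nonselective_curve(times, params, ModelVariant(3), wortmannin=wtm)
        if noise_sd > 0:
            a = a * rng.lognormal(-0.5 * noise_sd**2, noise_sd, size=a.shape)
        out[cond] = [TimeCourse(times, a, condition=cond, repeat_id="mean")]
    return out


@pytest.fixture
def pulse_datasets(nonselective_params):
    return make_pulse_datasets(nonselective_params)
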