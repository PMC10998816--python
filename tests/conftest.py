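import numpy as np
import pytest

from fermkin import Condition, StressParams, TimeCourse, simulate_batch, ze75_preset


def make_timecourse(
    times,
    biomass,
    ethanol,
    substrate=None,
    condition_id="c1",
    s_g0=150.0,
    **cond_kwargs,
):
    """Build a TimeCourse from plain sequences with sensible defaults."""
    cond = Condition(condition_id=condition_id, s_g0=s_g0, **cond_kwargs)
    return TimeCourse(
        condition=cond,
        times=np.asarray(times, dtype=float),
        biomass=np.asarray(biomass, dtype=float),
        ethanol=np.asarray(ethanol, dtype=float),
        substrate=None if substrate is None else np.asarray(substrate, dtype=float),
    )


@pytest.fixture
def exponential_tc():
    """Exact exponential growth X = 0.5 exp(0.12 t), linear ethanol."""
    t = np.arange(0.0, 28.0, 4.0)
    return make_timecourse(t, 0.5 * np.exp(0.12 * t), 1.0 * t, 150.0 - 2.0 * t)


@pytest.fixture(scope="session")
def default_noise_free_run():
    """One noise-free batch at the default preset (150 g/L glucose)."""
    params = ze75_preset(noise_cv=0.0)
    cond = Condition(condition_id="default", s_g0=params.s0, ph=4.5,
                     salinity="seawater")
    return params, simulate_batch(params, cond, StressParams())
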