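import numpy as np
import pytest

import shoalresp as sr


@pytest.fixture(scope="session")
def chamber():
    return sr.ChamberSpec()


@pytest.fixture(scope="session")
def default_config():
    return sr.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def noiseless_config():
    """All stochastic components off: exact mass-balance checks."""
    return sr.SimulationConfig(seed=1, activity_noise_sd=0.0,
                               optode_noise_sd=0.0,
                               shoal_effect_fixed=0.259)


@pytest.fixture(scope="session")
def mean_fish():
    return sr.FishRecord("f1", 1.84, 3.69)


@pytest.fixture(scope="session")
def default_trial(chamber, default_config, mean_fish):
    return sr.simulate_trial(chamber, mean_fish, "solitary", default_config)


@pytest.fixture(scope="session")
def default_slopes(chamber, default_config, default_trial):
    trace, _ = default_trial
    pre = sr.simulate_background_trial(chamber, default_config, "pre")
    post = sr.simulate_background_trial(chamber, default_config, "post")
    return sr.process_trial(trace, pre, post, chamber, 1.84)


def piecewise_trace(chamber, period_mo2, v_litres=None, o2_start=8.0):
    """Hand-built annotated trace: one exact linear decline per measurement
    period at MO2 = period_mo2[i] (mg O2/h), flat flush phases at o2_start.

    Independent of the simulator; used as a slope-pipeline oracle input.
    """
    v = chamber.inner_volume if v_litres is None else v_litres
    dt = chamber.sample_interval
    times, o2, phase = [], [], []
    t0 = 0.0
    for rate in period_mo2:
        tm = np.arange(t0, t0 + chamber.measure_duration, dt)
        times.append(tm)
        o2.append(o2_start - (rate / v) * (tm - t0) / 3600.0)
        phase.append(np.full(tm.size, "measure", dtype=object))
        tf = np.arange(t0 + chamber.measure_duration,
                       t0 + chamber.cycle_duration, dt)
        times.append(tf)
        o2.append(np.full(tf.size, o2_start))
        phase.append(np.full(tf.size, "flush", dtype=object))
        t0 += chamber.cycle_duration
    return sr.O2Trace(np.concatenate(times), np.concatenate(o2),
                      np.concatenate(phase), chamber=chamber)
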