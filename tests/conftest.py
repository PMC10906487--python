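import numpy as np
import pandas as pd
import pytest

from thermoperf.config import CycleSchedule, RespirometerSpec
from thermoperf.respirometry import O2Trace
from thermoperf.synthetic import RespirometrySimParams, simulate_o2_trace


@pytest.fixture
def schedule():
    """9-min closed / 3-min flush cycle with the standard 120/60 s trims."""
    return CycleSchedule(flush_duration=180.0, closed_duration=540.0)


@pytest.fixture
def spec():
    """160-mL loop, 10-mL fish, alpha 0.08 mg O2/L/%sat, 50-g fish."""
    return RespirometerSpec(
        loop_volume=0.160, fish_volume=0.010, alpha=0.08, mass=0.050
    )


@pytest.fixture
def zero_noise_params(schedule, spec):
    """Mono-exponential recovery trace with closed-form ground truth."""
    return RespirometrySimParams(
        true_smr=2.0,
        true_mmr=5.0,
        recovery_tau=1.0,
        schedule=schedule,
        spec=spec,
        duration_h=14.0,
        background_rate=0.0,
        noise_sd=0.0,
        sample_period_s=1.0,
    )


@pytest.fixture
def zero_noise_trace(zero_noise_params):
    return simulate_o2_trace(zero_noise_params)


def make_trace(times, o2, phases, fish_id="t", temperature=14.0):
    return O2Trace(
        fish_id=fish_id,
        test_temperature=temperature,
        data=pd.DataFrame(
            {"time_s": times, "o2_percent_sat": o2, "phase": phases}
        ),
    )


def linear_decline_trace(
    schedule, rate_pct_per_h, n_cycles=3, dt=5.0, n_background=0
):
    """Trace declining at a constant rate during every closed phase."""
    times, o2, phases = [], [], []
    total_cycles = n_cycles + n_background
    for c in range(total_cycles):
        start = c * schedule.period
        t = np.arange(start, start + schedule.period, dt)
        closed = t < start + schedule.closed_duration
        label = "background" if c >= n_cycles else "closed"
        phases.extend(label if cl else "flush" for cl in closed)
        o2.extend(
            np.where(
                closed, 100.0 - rate_pct_per_h * (t - start) / 3600.0, 100.0
            )
        )
        times.extend(t)
    return make_trace(np.array(times), np.array(o2), np.array(phases, object))
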