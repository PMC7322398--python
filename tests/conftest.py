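import numpy as np
import pytest

from guvfrap import FrameSchedule, FrapTrace, SpotGeometry


@pytest.fixture
def schedule():
    return FrameSchedule(n_pre=8, t_bleach=0.1, n_post=100, dt=0.2)


@pytest.fixture
def geometry():
    return SpotGeometry(w=2.0, area=400.0, t_bleach=0.1)


def make_trace(recovery, schedule=None, pre_value=100.0, geometry=None, **kw):
    """Build a FrapTrace from an explicit recovery-intensity array."""
    recovery = np.asarray(recovery, dtype=float)
    if schedule is None:
        schedule = FrameSchedule(n_pre=8, t_bleach=0.1, n_post=recovery.size, dt=0.2)
    if geometry is None:
        geometry = SpotGeometry(w=2.0, area=400.0, t_bleach=schedule.t_bleach)
    intensities = np.concatenate([np.full(schedule.n_pre, pre_value), recovery])
    return FrapTrace(
        times=schedule.times(),
        intensities=intensities,
        schedule=schedule,
        geometry=geometry,
        **kw,
    )


@pytest.fixture
def trace_factory():
    return make_trace
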