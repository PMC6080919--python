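import numpy as np
import pytest

from congression import SimParams, make_geometry


@pytest.fixture(scope="session")
def geometry():
    return make_geometry()


@pytest.fixture(scope="session")
def ap_point(geometry):
    return geometry.ap_point


@pytest.fixture
def default_params():
    return SimParams()


@pytest.fixture
def tiny_params():
    """Cheap but structurally complete simulation settings."""
    return SimParams(t_end=5.0, n_mt_per_aster=60, n_chromosomes=6, seed=11)


def make_two_phase_track(
    d0=30.0,
    switch_min=7.5,
    speed=9.22,
    frame_s=3.0,
    t_end_min=16.0,
    jitter=0.1,
    seed=0,
    t_x=15.0,
    t_m=12.5,
    p=None,
):
    """Hand-built two-phase track: exact advection toward p from distance
    d0, then straight transport at ``speed`` until 2 µm from p."""
    if p is None:
        p = np.array([0.0, 0.0, 35.0])
    rng = np.random.default_rng(seed)
    direction = np.array([0.0, 0.0, -1.0])
    x = p + d0 * direction
    times_s = np.arange(0.0, t_end_min * 60.0 + frame_s / 2, frame_s)
    pos = np.empty((len(times_s), 3))
    pos[0] = x
    for k in range(1, len(times_s)):
        t0, t1 = times_s[k - 1] / 60.0, times_s[k] / 60.0
        if t1 >= switch_min:
            to_p = p - x
            dist = np.linalg.norm(to_p)
            step = speed * frame_s / 60.0
            if dist > 2.0:
                x = x + to_p / dist * min(step, dist - 2.0)
        elif t0 <= t_m:
            frac = (t_x - min(t1, t_m)) / (t_x - t0)
            x = p + (x - p) * frac
        pos[k] = x
    if jitter:
        pos = pos + jitter * rng.standard_normal(pos.shape)
    return times_s, pos, p
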