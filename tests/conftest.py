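import numpy as np
import pytest

import movekde as mk


@pytest.fixture(scope="session")
def sim_track():
    """A moderately long simulated Brownian track with known parameters."""
    cfg = mk.SimConfig(eta2=100.0, gamma2=1.0, var_xy=25.0, var_z=4.0,
                       fix_interval=10.0, n_fixes=60, seed=11)
    track, truth = mk.simulate_track(cfg)
    return cfg, track, truth


@pytest.fixture(scope="session")
def sim_steps(sim_track):
    cfg, track, _ = sim_track
    return mk.classify_move_steps(track, mk.FilterConfig(t_max=20.0))


@pytest.fixture(scope="session")
def single_step():
    """One usable 60-minute move step from (0,0,0) to (100,0,0)."""
    err = mk.ErrorModel(var_xy=25.0, var_z=9.0)
    track = mk.build_track(
        [("a", 0.0, 0.0, 0.0, 0.0), ("a", 60.0, 100.0, 0.0, 0.0)], err
    )
    steps = mk.classify_move_steps(track, mk.FilterConfig(t_max=120.0))
    assert steps[0].usable
    return track, steps[0]


def make_spec(lo, hi, cell):
    """Grid spec covering [lo, hi] per axis with the given voxel edges."""
    counts = [max(1, int(np.ceil((h - l) / c))) for l, h, c in zip(lo, hi, cell)]
    return mk.GridSpec3D(
        x0=lo[0], y0=lo[1], z0=lo[2],
        hx=cell[0] / 2, hy=cell[1] / 2, hz=cell[2] / 2,
        I=counts[1], J=counts[0], K=counts[2],
    )
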