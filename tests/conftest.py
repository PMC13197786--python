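import numpy as np
import pandas as pd
import pytest

from rnadyn import MotionParams, render_movie, sim_trajectories


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_spot_image():
    """Noise-free rendered spot at a known subpixel position."""
    spots = pd.DataFrame(
        [{"frame": 0, "x_px": 10.30, "y_px": 7.60, "amplitude": 1000.0}]
    )
    stack, truth = render_movie(
        spots,
        shape=(24, 24),
        background=50.0,
        read_noise_sd=0.0,
        poisson_noise=False,
    )
    return stack.frame(0), truth.entities


@pytest.fixture
def brownian_trajectories():
    params = MotionParams(
        "diffusive", D_um2_s=0.05, loc_noise_sigma_um=0.0, n_frames=40, dt_s=0.03
    )
    trajs, truth = sim_trajectories(params, n_per_class=20, seed=99)
    return trajs, truth
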