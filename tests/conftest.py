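import numpy as np
import pytest

import cascadefish as cf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    roi = np.zeros((16, 16), dtype=bool)
    roi[1:-1, 1:-1] = True
    return roi


@pytest.fixture
def tiny_cascade_movie(square_roi):
    """Noise-free impulse-rendered movie with one 3-frame, 5-pixel cascade."""
    params = cf.SynthMovieParams(
        height=16,
        width=16,
        n_frames=400,
        noise_sd=0.0,
        drift_amplitude=0.0,
        transient_shape="impulse",
        seed=7,
    )
    pixels = [(5, 5), (5, 6), (5, 7), (6, 6), (6, 7)]
    cascade = cf.InjectedCascade(
        start_frame=150, per_frame_pixel_sets=[pixels] * 3, amplitude=1.0
    )
    movie, truth = cf.generate_mesoscale_movie(params, [cascade], square_roi)
    return movie, truth, square_roi
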