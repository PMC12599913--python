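import numpy as np
import pytest

from punctakit import DetectionParams, RestrictionParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def det_params():
    """Tuned bright-reporter detection settings used across tests."""
    return DetectionParams(sensitivity=0.2, neighborhood_size=15)


@pytest.fixture
def restr_params():
    """Standard restriction: 3 px y-edge band, 5 px^2 minimum area."""
    return RestrictionParams(y_edge_px=3, min_area_px2=5.0)


def gaussian_spot(shape, center, amplitude, sigma):
    """Noiseless Gaussian punctum contribution on a zero background."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2.0 * sigma**2)
    )


def two_peak_scene(seed, separation=8, sigma=2.0, amplitude=100.0, shape=(20, 40)):
    """Two equal Gaussian puncta whose threshold mask merges into one blob."""
    rng = np.random.default_rng(seed)
    cy = shape[0] / 2.0
    cx = shape[1] / 2.0
    c1 = (cy, cx - separation / 2.0)
    c2 = (cy, cx + separation / 2.0)
    img = (
        10.0
        + gaussian_spot(shape, c1, amplitude, sigma)
        + gaussian_spot(shape, c2, amplitude, sigma)
        + rng.normal(0.0, 1.0, shape)
    )
    peaks = (
        (int(round(c1[0])), int(round(c1[1]))),
        (int(round(c2[0])), int(round(c2[1]))),
    )
    return img, peaks


def naive_window_mean(image, window):
    """Brute-force edge-replicated sliding-window mean (oracle)."""
    from numpy.lib.stride_tricks import sliding_window_view

    pad = window // 2
    padded = np.pad(np.asarray(image, dtype=float), pad, mode="edge")
    return sliding_window_view(padded, (window, window)).mean(axis=(2, 3))


def block_pair_channels(shape=(20, 120), n_blocks=3, coverage_cols=4):
    """Two-channel scene of rectangular puncta with exact known coverage.

    Channel 1 holds 4 x 10 blocks; channel 2 covers exactly the first
    ``coverage_cols`` columns of each (coverage_cols/10 of its area).
    Crisp 0/100 intensities make the adaptive threshold recover the
    drawn rectangles exactly.
    """
    ch1 = np.zeros(shape)
    ch2 = np.zeros(shape)
    for b in range(n_blocks):
        r0, c0 = 8, 15 + 35 * b
        ch1[r0 : r0 + 4, c0 : c0 + 10] = 100.0
        ch2[r0 : r0 + 4, c0 : c0 + coverage_cols] = 100.0
    return ch1, ch2
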