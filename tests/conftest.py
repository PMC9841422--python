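"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from smolkin import simulate


def naive_piecewise_sse(times, values, refine=False):
    """Independent exhaustive-grid OLS oracle for the piecewise-linear fit.

    For every (a, b) pair on frame boundaries, clips the time axis and
    solves the two-parameter OLS directly with lstsq — no prefix sums, no
    shared code with the implementation.  Returns (best_sse, m, t, a, b).
    """
    x = np.asarray(times, float)
    y = np.asarray(values, float)
    n = x.size
    sy = y.sum()
    syy_c = float(np.sum((y - y.mean()) ** 2))
    best = (np.inf, 0.0, 0.0, x[0], x[0])
    for ia in range(n):
        a = x[ia]
        b = x[ia:]                                     # all b >= a
        z = np.minimum(np.maximum(x[None, :], a), b[:, None])
        sz = z.sum(axis=1)
        szz_c = (z * z).sum(axis=1) - sz * sz / n
        szy_c = z @ y - sz * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(szz_c > 1e-12, szy_c / np.where(szz_c > 0, szz_c, 1.0), 0.0)
        sse = syy_c - m * szy_c
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            t = (sy - m[j] * sz[j]) / n
            best = (float(sse[j]), float(m[j]), float(t), float(a), float(b[j]))
    return best


def naive_best_split(values):
    """Exhaustive single-split two-level model oracle.

    Returns (split_index, sse) minimising within-segment sum of squares;
    the split index is the first index of the right segment.
    """
    y = np.asarray(values, float)
    best = (1, np.inf)
    for k in range(1, y.size):
        sse = np.sum((y[:k] - y[:k].mean()) ** 2) + \
            np.sum((y[k:] - y[k:].mean()) ** 2)
        if sse < best[1]:
            best = (k, float(sse))
    return best


@pytest.fixture
def digestion_program():
    return simulate.KineticProgram(kind="digestion", rate=26.2, start_time=10.0)


@pytest.fixture
def small_scene():
    """A compact two-molecule scene for fast movie tests."""
    return simulate.SceneConfig(
        field_size=(48, 48), pixel_size=0.16, spot_density=0.1,
        frame_interval=0.5, n_frames=20, psf_sigma=1.0,
        photon_scale=200.0, background=10.0, read_noise_sigma=2.0,
        shot_noise=True, seed=7,
    )
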