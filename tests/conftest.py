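"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from nbseg.levelset_core import heaviside


@pytest.fixture
def circle_sdf():
    """Factory for exact signed-distance fields of circles (interior < 0)."""

    def make(shape=(64, 64), center=(32.0, 32.0), radius=10.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(yy - center[0], xx - center[1]) - radius

    return make


@pytest.fixture
def disk_image():
    """Noiseless 64x64 disk fixture: 0.9 disk (R=12) on 0.1 background."""
    yy, xx = np.mgrid[0:64, 0:64]
    truth = np.hypot(yy - 32, xx - 32) < 12
    image = np.where(truth, 0.9, 0.1)
    return image, truth


def brute_local_means(channel, H, offsets):
    """Direct per-pixel evaluation of the windowed interior/exterior means.

    Pure-python double loop over pixels and ball offsets, clipped at the
    image borders; the independent oracle for the convolution path.
    """
    h, w = channel.shape
    u = np.zeros((h, w))
    v = np.zeros((h, w))
    u_def = np.zeros((h, w), dtype=bool)
    v_def = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            nu = du = nv = dv = 0.0
            for dy, dx in offsets:
                y, x = i + dy, j + dx
                if 0 <= y < h and 0 <= x < w:
                    nu += H[y, x] * channel[y, x]
                    du += H[y, x]
                    nv += (1.0 - H[y, x]) * channel[y, x]
                    dv += 1.0 - H[y, x]
            if du > 1e-9:
                u[i, j] = nu / du
                u_def[i, j] = True
            if dv > 1e-9:
                v[i, j] = nv / dv
                v_def[i, j] = True
    return u, v, u_def, v_def


def brute_global_means(channel, H):
    """Scalar-loop global interior/exterior means."""
    nu = du = nv = dv = 0.0
    for i in range(channel.shape[0]):
        for j in range(channel.shape[1]):
            nu += H[i, j] * channel[i, j]
            du += H[i, j]
            nv += (1 - H[i, j]) * channel[i, j]
            dv += 1 - H[i, j]
    return nu / du, nv / dv


def random_phi(rng, shape=(32, 32)):
    """Random smooth level-set-like field with a guaranteed zero crossing."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(size=shape), 3.0)
    f -= np.median(f)
    return f * 8.0


def heaviside_mass_ok(phi, epsilon=1.5):
    H = heaviside(phi, epsilon)
    return H.sum() > 1e-9 and (1 - H).sum() > 1e-9
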