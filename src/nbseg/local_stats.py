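"""Ball-mask neighborhoods and local/global interior-exterior means.

The driving statistic of the narrow-band model is the pair of intensity means
inside and outside the contour, taken both globally over the image (``u``,
``v``) and locally within a radius-``r`` ball around each pixel (``u_x``,
``v_x``).  Membership of the ball is strict: offsets with Euclidean norm
``< r``.  All means weight pixels by the smoothed Heaviside of the level-set
field, consistent with the global-mean definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve

from .errors import EmptyPhaseError, InvalidParameterError

__all__ = ["BallMask", "LocalStatsField", "ball_mask", "global_means", "local_means"]

#: below this windowed Heaviside mass a local mean is flagged undefined
MASS_TOL = 1e-9

#: kernels at or below this many taps use exact direct convolution
_DIRECT_KERNEL_MAX = 13 * 13


@dataclass(frozen=True)
class BallMask:
    """Set of integer pixel offsets with Euclidean norm strictly below ``radius``."""

    radius: float
    offsets: tuple
    kernel: np.ndarray

    def __len__(self) -> int:
        return len(self.offsets)


def ball_mask(r: float) -> BallMask:
    """Build the radius-``r`` ball of integer offsets (strict ``||d|| < r``).

    ``r = 1`` gives the singleton {(0,0)}; ``r = 2`` the 9-offset 3x3 block.
    """
    if r <= 0:
        raise InvalidParameterError("ball radius must be positive")
    k = int(np.ceil(r)) - 1
    dy, dx = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1), indexing="ij")
    inside = dy**2 + dx**2 < r**2
    offsets = tuple(zip(dy[inside].tolist(), dx[inside].tolist()))
    return BallMask(radius=float(r), offsets=offsets, kernel=inside.astype(float))


@dataclass
class LocalStatsField:
    """Per-pixel local means and scalar global means for one channel.

    ``u_local``/``v_local`` are the windowed interior/exterior means; where a
    window contains (almost) no mass of a phase the corresponding entry is
    flagged undefined in ``u_defined``/``v_defined`` and must contribute zero
    force.
    """

    u_local: np.ndarray
    v_local: np.ndarray
    u_defined: np.ndarray
    v_defined: np.ndarray
    u_global: float
    v_global: float
    channel_index: int = 0


def _windowed_sum(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum of ``a`` over the ball window at every pixel, clipped at borders."""
    if kernel.size <= _DIRECT_KERNEL_MAX:
        return ndi.convolve(a, kernel, mode="constant", cval=0.0)
    out = fftconvolve(a, kernel, mode="same")
    return out


def global_means(channel: np.ndarray, H_field: np.ndarray) -> tuple:
    """Global interior/exterior means ``u = sum(H I)/sum(H)``, ``v`` likewise.

    Raises :class:`EmptyPhaseError` when either phase carries no Heaviside
    mass.
    """
    channel = np.asarray(channel, dtype=float)
    H = np.asarray(H_field, dtype=float)
    m_in = H.sum()
    m_out = (1.0 - H).sum()
    if m_in <= MASS_TOL or m_out <= MASS_TOL:
        raise EmptyPhaseError("one phase has no Heaviside mass")
    u = float((H * channel).sum() / m_in)
    v = float(((1.0 - H) * channel).sum() / m_out)
    return u, v


def local_means(
    channel: np.ndarray,
    H_field: np.ndarray,
    mask: BallMask,
    at: np.ndarray | None = None,
    channel_index: int = 0,
) -> LocalStatsField:
    """Windowed interior/exterior means around every pixel.

    Windows are clipped at image borders.  Values are computed on the full
    grid by windowed sums (identical to the direct per-pixel definition);
    ``at`` only documents the pixels the caller will read.  Pixels whose
    window holds no interior (resp. exterior) mass are flagged undefined
    rather than raising: band pixels far from the interface legitimately see
    a single phase.
    """
    channel = np.asarray(channel, dtype=float)
    H = np.asarray(H_field, dtype=float)
    kern = mask.kernel
    den_u = _windowed_sum(H, kern)
    den_v = _windowed_sum(1.0 - H, kern)
    num_u = _windowed_sum(H * channel, kern)
    num_v = _windowed_sum((1.0 - H) * channel, kern)
    u_def = den_u > MASS_TOL
    v_def = den_v > MASS_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        u_loc = np.where(u_def, num_u / np.where(u_def, den_u, 1.0), 0.0)
        v_loc = np.where(v_def, num_v / np.where(v_def, den_v, 1.0), 0.0)
    u, v = global_means(channel, H)
    return LocalStatsField(
        u_local=u_loc,
        v_local=v_loc,
        u_defined=u_def,
        v_defined=v_def,
        u_global=u,
        v_global=v,
        channel_index=channel_index,
    )
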