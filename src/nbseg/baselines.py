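"""Comparison models: vectorial multiphase Chan-Vese and channel-wise CV.

Both baselines are global piecewise-constant models driven by per-pixel
squared residuals against region means, evolved over the full image domain
(no narrow band, no local statistics).

*Vectorial multiphase CV* uses two level sets whose Heaviside products carve
the image into four phases; each phase has one mean color ``c_ab`` and the
energy is the channel-averaged squared residual per phase plus the two
contour lengths.

*STP-CV* runs the classical two-phase CV model independently in each channel
(interior mean ``c1``, exterior mean ``c2``) and then combines the channel
contours with the multichannel sign-sequence labeling.  The data force is
oriented for the phi<0-interior convention: a pixel that fits the interior
mean is pushed to negative phi.

Both baselines share the compact cosine-regularized Dirac of the level-set
core (all models are run with the same regularization parameters), but they
apply no per-iteration Gaussian smoothing of phi: that smoothing step is
part of the narrow-band loop, not of these classical formulations, whose
only regularizer is the explicit length term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyPhaseError, InvalidParameterError
from .levelset_core import (
    BinaryInitField,
    curvature,
    dirac,
    heaviside,
    reinitialize,
    smooth_sdf,
)
from .local_stats import MASS_TOL
from .msc_combine import RegionLabeling, combine

__all__ = [
    "dirac_global",
    "MultiphaseState",
    "VCVConfig",
    "STPCVConfig",
    "phase_means",
    "vcv_energy",
    "vcv_evolve",
    "stpcv_step",
    "stpcv_run",
]

_STATIONARY_TOL = 1e-12


def dirac_global(phi, epsilon: float = 1.5):
    """Cauchy-kernel regularized Dirac with global support.

    ``eps / (pi (eps^2 + phi^2))`` never vanishes, so the descent acts on
    every level curve: any pixel in the domain can switch phase.  This is the
    regularization the classical CV formulations use to avoid dependence on
    the initial contour -- and the mechanism by which their global-mean
    forces nucleate isolated noise specks far from the contour.  The slow
    far-field motion also makes the interior mask move in bursts, hence the
    longer convergence patience of the baseline configs.
    """
    phi = np.asarray(phi, dtype=float)
    return epsilon / (np.pi * (epsilon**2 + phi**2))


@dataclass
class MultiphaseState:
    """Two level sets and the 4 x C matrix of phase mean colors.

    Phase (a, b) with a, b in {1, 2} is weighted by
    ``Ha(phi1) * Hb(phi2)`` where ``H1 = H`` (interior) and ``H2 = 1 - H``.
    ``c[idx]`` rows are ordered (c11, c12, c21, c22).
    """

    phi1: np.ndarray
    phi2: np.ndarray
    c: np.ndarray  # (4, C)


@dataclass(frozen=True)
class VCVConfig:
    """Parameters of the vectorial multiphase CV descent."""

    mu: float = 0.3  # curvature (length) weight of the descent
    epsilon: float = 1.5
    dt: float = 0.45
    reinit_every: int = 5  # 0 = never reinitialize
    smooth_sigma: float = 0.0
    max_iter: int = 600
    convergence_patience: int = 10

    def __post_init__(self) -> None:
        if self.mu < 0 or self.epsilon <= 0 or self.dt <= 0:
            raise InvalidParameterError("mu >= 0 and epsilon, dt > 0 required")


@dataclass(frozen=True)
class STPCVConfig:
    """Parameters of the per-channel CV model."""

    mu: float = 0.2  # curvature (length) weight
    nu_area: float = 0.0  # interior-area weight
    lambda1: float = 1.0
    lambda2: float = 1.0
    epsilon: float = 1.5
    dt: float = 0.45
    reinit_every: int = 5  # 0 = never reinitialize
    smooth_sigma: float = 0.0
    max_iter: int = 600
    convergence_patience: int = 10

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise InvalidParameterError("lambda1 and lambda2 must be positive")
        if self.epsilon <= 0 or self.dt <= 0:
            raise InvalidParameterError("epsilon and dt must be positive")


def _phase_weights(phi1, phi2, epsilon):
    h1 = heaviside(phi1, epsilon)
    h2 = heaviside(phi2, epsilon)
    return (h1 * h2, h1 * (1 - h2), (1 - h1) * h2, (1 - h1) * (1 - h2)), (h1, h2)


def phase_means(image: np.ndarray, phi1, phi2, epsilon: float = 1.5,
                previous: np.ndarray | None = None) -> np.ndarray:
    """Mean color of each of the four phases; empty phases keep ``previous``."""
    image = np.asarray(image, dtype=float)
    weights, _ = _phase_weights(phi1, phi2, epsilon)
    c = np.zeros((4, image.shape[-1]))
    for a, wgt in enumerate(weights):
        mass = wgt.sum()
        if mass > MASS_TOL:
            c[a] = (wgt[..., None] * image).sum(axis=(0, 1)) / mass
        elif previous is not None:
            c[a] = previous[a]
        else:
            raise EmptyPhaseError(f"phase {a} is empty and no previous mean exists")
    return c


def vcv_energy(state: MultiphaseState, image: np.ndarray, mu: float = 1.0,
               epsilon: float = 1.5) -> float:
    """Vectorial multiphase CV energy.

    Channel-averaged squared residual of each phase against its mean color,
    plus ``mu`` times the total variation of the two Heavisides (the contour
    lengths); ``mu = 1`` reproduces the unweighted length terms of the
    defining energy.
    """
    image = np.asarray(image, dtype=float)
    weights, (h1, h2) = _phase_weights(state.phi1, state.phi2, epsilon)
    nchan = image.shape[-1]
    data = 0.0
    for a, wgt in enumerate(weights):
        resid = ((image - state.c[a]) ** 2).sum(axis=-1) / nchan
        data += float((resid * wgt).sum())
    length = 0.0
    for h in (h1, h2):
        gy, gx = np.gradient(h)
        length += float(np.hypot(gy, gx).sum())
    return data + mu * length


def _vcv_rates(image, phi1, phi2, c, cfg: VCVConfig):
    """Descent rates for both level sets at the current phase means."""
    image = np.asarray(image, dtype=float)
    nchan = image.shape[-1]
    e = [((image - c[a]) ** 2).sum(axis=-1) / nchan for a in range(4)]
    _, (h1, h2) = _phase_weights(phi1, phi2, cfg.epsilon)
    d1 = dirac(phi1, cfg.epsilon)
    d2 = dirac(phi2, cfg.epsilon)
    # interior of each phi is phi < 0 (H = 1); raising phi moves mass from
    # the 1x phases to the 2x phases, so descent follows the residual gaps
    l1 = d1 * (cfg.mu * curvature(phi1) + (e[0] - e[2]) * h2 + (e[1] - e[3]) * (1 - h2))
    l2 = d2 * (cfg.mu * curvature(phi2) + (e[0] - e[1]) * h1 + (e[2] - e[3]) * (1 - h1))
    return l1, l2


def vcv_evolve(
    image: np.ndarray,
    init1: BinaryInitField,
    init2: BinaryInitField,
    cfg: VCVConfig = VCVConfig(),
    track_energy: bool = True,
):
    """Alternating gradient descent on the two level sets.

    Phase means are recomputed each iteration (empty phases carry the
    previous mean).  Returns ``(state, labeling, energy_trace, converged)``
    where ``labeling`` is the 4-phase sign-sequence labeling of
    ``(phi1, phi2)``.
    """
    image = np.asarray(image, dtype=float)
    # binary start: |phi| = 1 < epsilon, so the first iterations act on the
    # whole domain (same bootstrap as the narrow-band loop)
    phi1 = np.asarray(init1.values, dtype=float).copy()
    phi2 = np.asarray(init2.values, dtype=float).copy()
    c = phase_means(image, phi1, phi2, cfg.epsilon)
    trace: list = []
    prev_labels = combine([phi1, phi2]).labels
    stable = 0
    converged = False
    for k in range(cfg.max_iter):
        c = phase_means(image, phi1, phi2, cfg.epsilon, previous=c)
        if track_energy:
            trace.append(vcv_energy(MultiphaseState(phi1, phi2, c), image,
                                    cfg.mu, cfg.epsilon))
        l1, l2 = _vcv_rates(image, phi1, phi2, c, cfg)
        max_l = max(float(np.abs(l1).max()), float(np.abs(l2).max()))
        if max_l > _STATIONARY_TOL:
            phi1 = phi1 + (cfg.dt / max_l) * l1
            phi2 = phi2 + (cfg.dt / max_l) * l2
            if cfg.smooth_sigma > 0:
                phi1 = smooth_sdf(phi1, cfg.smooth_sigma)
                phi2 = smooth_sdf(phi2, cfg.smooth_sigma)
            if cfg.reinit_every and (k + 1) % cfg.reinit_every == 0:
                ins1 = phi1 < 0
                if ins1.any() and not ins1.all():
                    phi1 = reinitialize(phi1)
                ins2 = phi2 < 0
                if ins2.any() and not ins2.all():
                    phi2 = reinitialize(phi2)
        labels = combine([phi1, phi2]).labels
        stable = stable + 1 if np.array_equal(labels, prev_labels) else 0
        prev_labels = labels
        if stable >= cfg.convergence_patience:
            converged = True
            break
    c = phase_means(image, phi1, phi2, cfg.epsilon, previous=c)
    state = MultiphaseState(phi1, phi2, c)
    return state, combine([phi1, phi2]), trace, converged


def _cv_means(channel: np.ndarray, phi: np.ndarray, epsilon: float):
    h = heaviside(phi, epsilon)
    m1 = h.sum()
    m2 = (1 - h).sum()
    if m1 <= MASS_TOL or m2 <= MASS_TOL:
        raise EmptyPhaseError("a CV phase has no Heaviside mass")
    c1 = float((h * channel).sum() / m1)
    c2 = float(((1 - h) * channel).sum() / m2)
    return c1, c2


def stpcv_step(phi: np.ndarray, channel: np.ndarray, cfg: STPCVConfig) -> np.ndarray:
    """One normalized forward-Euler update of the per-channel CV flow.

    Rate: ``delta(phi) * (mu*kappa + nu_area + lambda1*(I-c1)^2 -
    lambda2*(I-c2)^2)`` with ``c1``/``c2`` the interior/exterior means; a
    pixel fitting the interior mean is driven to phi < 0.
    """
    phi = np.asarray(phi, dtype=float)
    channel = np.asarray(channel, dtype=float)
    c1, c2 = _cv_means(channel, phi, cfg.epsilon)
    delta = dirac(phi, cfg.epsilon)
    rate = delta * (
        cfg.mu * curvature(phi)
        + cfg.nu_area
        + cfg.lambda1 * (channel - c1) ** 2
        - cfg.lambda2 * (channel - c2) ** 2
    )
    max_l = float(np.abs(rate).max())
    if max_l <= _STATIONARY_TOL:
        return phi.copy()
    return phi + (cfg.dt / max_l) * rate


def stpcv_run(
    image: np.ndarray,
    inits,
    cfg: STPCVConfig = STPCVConfig(),
):
    """Per-channel CV evolution to convergence, then MSC labeling.

    ``inits`` is one :class:`BinaryInitField` per channel (or a single one
    reused for all).  Returns ``(labeling, phis, converged_flags)``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None]
    nchan = image.shape[-1]
    if isinstance(inits, BinaryInitField):
        inits = [inits] * nchan
    phis = []
    flags = []
    for i in range(nchan):
        phi = np.asarray(inits[i].values, dtype=float).copy()
        prev_interior = phi < 0
        stable = 0
        converged = False
        for k in range(cfg.max_iter):
            inside = phi < 0
            if not inside.any() or inside.all():
                break
            phi = stpcv_step(phi, image[..., i], cfg)
            if cfg.smooth_sigma > 0:
                phi = smooth_sdf(phi, cfg.smooth_sigma)
            if cfg.reinit_every and (k + 1) % cfg.reinit_every == 0:
                ins = phi < 0
                if ins.any() and not ins.all():
                    phi = reinitialize(phi)
            interior = phi < 0
            stable = stable + 1 if np.array_equal(interior, prev_interior) else 0
            prev_interior = interior
            if stable >= cfg.convergence_patience:
                converged = True
                break
        phis.append(phi)
        flags.append(converged)
    return combine(phis), phis, flags
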