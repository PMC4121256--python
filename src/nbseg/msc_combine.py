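"""Multichannel segmentation combination (MSC).

Each of the N channels is segmented by its own level set; a pixel's region
identity is the N-tuple of contour signs, ``s_i = 1`` if ``phi_i > 0``
(exterior) and ``s_i = 0`` otherwise (interior; a pixel exactly on the
contour takes the interior sign).  The tuple is packed into an integer label
``sum_i s_i * 2^(N-1-i)`` with the first channel most significant, giving up
to ``2^N`` distinct regions — 8 for an RGB image with one level set per
channel.  Channel order is fixed as stored (R, G, B for color input), so
labels are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .levelset_core import ChannelLevelSet

__all__ = ["RegionLabeling", "combine", "label_to_color"]


@dataclass
class RegionLabeling:
    """Per-pixel sign sequences and their packed integer labels."""

    signs: np.ndarray  # (H, W, N) uint8 in {0, 1}
    labels: np.ndarray  # (H, W) int, in [0, 2^N)
    n_channels: int

    @property
    def n_regions(self) -> int:
        """Number of distinct labels actually present."""
        return int(np.unique(self.labels).size)

    def region_mask(self, label: int) -> np.ndarray:
        """Boolean mask of one region."""
        return self.labels == label


def combine(phis) -> RegionLabeling:
    """Combine N per-channel level sets into a region labeling.

    Accepts a sequence of 2-D phi arrays or :class:`ChannelLevelSet` objects,
    all of the same shape.
    """
    fields = []
    for p in phis:
        arr = p.phi if isinstance(p, ChannelLevelSet) else np.asarray(p, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError("each level-set field must be 2-D")
        fields.append(arr)
    if not fields:
        raise InvalidInputError("need at least one level-set field")
    shape = fields[0].shape
    if any(f.shape != shape for f in fields):
        raise InvalidInputError("all level-set fields must share one shape")
    n = len(fields)
    signs = np.stack([(f > 0).astype(np.uint8) for f in fields], axis=-1)
    weights = 2 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    labels = (signs.astype(np.int64) * weights).sum(axis=-1)
    return RegionLabeling(signs=signs, labels=labels, n_channels=n)


def label_to_color(labeling: RegionLabeling, palette) -> np.ndarray:
    """Map labels to colors deterministically (same label -> same color).

    ``palette`` is a sequence of at least ``2^N`` RGB triples in [0, 1]; the
    label value indexes the palette directly, so the mapping is injective on
    distinct labels.
    """
    palette = np.asarray(palette, dtype=float)
    if palette.ndim != 2 or palette.shape[1] != 3:
        raise InvalidParameterError("palette must be a sequence of RGB triples")
    needed = int(labeling.labels.max()) + 1
    if palette.shape[0] < needed:
        raise InvalidParameterError(
            f"palette has {palette.shape[0]} colors, need at least {needed}"
        )
    return palette[labeling.labels]


#: default palette for up to 8 regions (3 channels)
DEFAULT_PALETTE = np.array(
    [
        (0.00, 0.00, 0.00),
        (0.12, 0.47, 0.71),
        (0.17, 0.63, 0.17),
        (0.84, 0.15, 0.16),
        (1.00, 0.50, 0.05),
        (0.58, 0.40, 0.74),
        (0.55, 0.34, 0.29),
        (0.95, 0.95, 0.95),
    ]
)
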