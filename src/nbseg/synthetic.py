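"""Seeded generator of colored-shape test scenes and noise models.

Scenes are hard-edged rasterizations (no anti-aliasing) of circles,
rectangles and stars in flat colors on a contrasting background, so the
ground-truth label image is pixel-exact by construction: later shapes
overdraw earlier ones, label 0 is the background and label k the k-th shape.

Three noise models emulate the degradations used in the reference
experiments, all parameterized on the [0,1] intensity scale:

- ``gaussian``: additive i.i.d. N(0, v) per pixel and channel, clipped;
- ``salt_pepper``: a fraction d of pixels set to 0 or 1 (equal probability,
  all channels of a corrupted pixel together);
- ``multiplicative`` (speckle): I + n*I with n ~ N(0, v), clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.draw import disk as draw_disk, polygon as draw_polygon

from .errors import InvalidSpecError

__all__ = [
    "Shape",
    "SceneSpec",
    "NoiseSpec",
    "render",
    "add_noise",
    "channel_truth",
    "color_truth",
    "scene",
    "SCENES",
]


@dataclass(frozen=True)
class Shape:
    """One flat-colored shape.

    ``kind`` is ``circle`` (params: center (row, col), radius), ``rectangle``
    (params: top-left (row, col), height, width) or ``star`` (params: center,
    outer radius; optional inner radius = 0.5*outer, points = 5, rotation).
    """

    kind: str
    params: dict
    color: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "rectangle", "star"):
            raise InvalidSpecError(f"unknown shape kind {self.kind!r}")
        c = np.asarray(self.color, dtype=float)
        if c.shape != (3,) or (c < 0).any() or (c > 1).any():
            raise InvalidSpecError("shape color must be an RGB triple in [0,1]")


@dataclass(frozen=True)
class SceneSpec:
    """Canvas, background color and an ordered list of shapes."""

    size: tuple
    background: tuple
    shapes: tuple
    name: str = "scene"

    def __post_init__(self) -> None:
        b = np.asarray(self.background, dtype=float)
        if b.shape != (3,) or (b < 0).any() or (b > 1).any():
            raise InvalidSpecError("background must be an RGB triple in [0,1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model and strength (variance for gaussian/multiplicative,
    density for salt_pepper), plus the RNG seed."""

    kind: str
    amount: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "salt_pepper", "multiplicative", "none"):
            raise InvalidSpecError(f"unknown noise kind {self.kind!r}")
        if self.amount < 0:
            raise InvalidSpecError("noise amount must be non-negative")
        if self.kind == "salt_pepper" and self.amount > 1:
            raise InvalidSpecError("salt-and-pepper density must be in [0,1]")


def _star_vertices(center, r_outer, r_inner, n_points, rotation):
    angles = rotation + np.arange(2 * n_points) * np.pi / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    rows = center[0] - radii * np.cos(angles)
    cols = center[1] + radii * np.sin(angles)
    return rows, cols


def _shape_pixels(shape: Shape, canvas: tuple):
    h, w = canvas
    if shape.kind == "circle":
        center = shape.params["center"]
        radius = shape.params["radius"]
        if (
            center[0] - radius < 0
            or center[1] - radius < 0
            or center[0] + radius > h - 1
            or center[1] + radius > w - 1
        ):
            raise InvalidSpecError("circle extends outside the canvas")
        return draw_disk(center, radius, shape=canvas)
    if shape.kind == "rectangle":
        r0, c0 = shape.params["top_left"]
        hh, ww = shape.params["height"], shape.params["width"]
        if r0 < 0 or c0 < 0 or r0 + hh > h or c0 + ww > w:
            raise InvalidSpecError("rectangle extends outside the canvas")
        rr, cc = np.meshgrid(np.arange(r0, r0 + hh), np.arange(c0, c0 + ww), indexing="ij")
        return rr.ravel(), cc.ravel()
    # star
    center = shape.params["center"]
    r_outer = shape.params["radius"]
    r_inner = shape.params.get("inner_radius", 0.5 * r_outer)
    n_points = shape.params.get("points", 5)
    rotation = shape.params.get("rotation", 0.0)
    rows, cols = _star_vertices(center, r_outer, r_inner, n_points, rotation)
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        raise InvalidSpecError("star extends outside the canvas")
    return draw_polygon(rows, cols, shape=canvas)


def render(spec: SceneSpec):
    """Rasterize a scene.

    Returns ``(image, truth_labels)``: a float (H, W, 3) image in [0,1] and
    an int (H, W) label field with 0 for background and k for the k-th shape
    (1-based, later shapes overdraw earlier ones).  Deterministic.
    """
    h, w = spec.size
    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.asarray(spec.background, dtype=float)
    labels = np.zeros((h, w), dtype=np.int64)
    for k, shape in enumerate(spec.shapes, start=1):
        rr, cc = _shape_pixels(shape, (h, w))
        image[rr, cc] = np.asarray(shape.color, dtype=float)
        labels[rr, cc] = k
    return image, labels


def color_truth(spec: SceneSpec):
    """Ground-truth labeling by distinct drawn color.

    Pixels sharing a color share a label (0 = background, then colors by
    first appearance).  This is the resolution at which the sign-sequence
    combination can distinguish regions: same-colored shapes necessarily
    share a label.  Returns ``(labels, colors)``.
    """
    image, shape_labels = render(spec)
    colors = [tuple(np.asarray(spec.background, dtype=float))]
    for s in spec.shapes:
        col = tuple(np.asarray(s.color, dtype=float))
        if col not in colors:
            colors.append(col)
    labels = np.zeros(shape_labels.shape, dtype=np.int64)
    for k, col in enumerate(colors):
        labels[np.all(image == np.array(col), axis=-1)] = k
    return labels, colors


def channel_truth(spec: SceneSpec, channel: int) -> np.ndarray:
    """Ground-truth 'component present' mask for one channel.

    A pixel belongs to the channel-``channel`` foreground iff the color drawn
    there has that component at or above 0.5.
    """
    image, _ = render(spec)
    return image[..., channel] >= 0.5


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply the seeded noise model; amount 0 (or kind 'none') is identity."""
    image = np.asarray(image, dtype=float)
    if spec.kind == "none" or spec.amount == 0:
        return image.copy()
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian":
        out = image + rng.normal(0.0, np.sqrt(spec.amount), size=image.shape)
        return np.clip(out, 0.0, 1.0)
    if spec.kind == "multiplicative":
        out = image + image * rng.normal(0.0, np.sqrt(spec.amount), size=image.shape)
        return np.clip(out, 0.0, 1.0)
    # salt and pepper: corrupt whole pixels across channels
    out = image.copy()
    hit = rng.random(image.shape[:2]) < spec.amount
    salt = rng.random(image.shape[:2]) < 0.5
    if image.ndim == 3:
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
    else:
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
    return out


# ---------------------------------------------------------------------------
# bundled demonstration scenes
# ---------------------------------------------------------------------------

_LO, _HI = 0.1, 0.9  # channel components used by all bundled scenes


def _three_disks() -> SceneSpec:
    """Three disks (yellow, blue, red) on a white background."""
    return SceneSpec(
        size=(128, 128),
        background=(_HI, _HI, _HI),
        shapes=(
            Shape("circle", {"center": (34, 64), "radius": 18}, (_HI, _HI, _LO)),
            Shape("circle", {"center": (88, 36), "radius": 18}, (_LO, _LO, _HI)),
            Shape("circle", {"center": (88, 92), "radius": 18}, (_HI, _LO, _LO)),
        ),
        name="fig3",
    )


def _four_color_shapes() -> SceneSpec:
    """Many shapes in four colors (white background + R, G, B objects)."""
    return SceneSpec(
        size=(128, 128),
        background=(_HI, _HI, _HI),
        shapes=(
            Shape("circle", {"center": (20, 22), "radius": 10}, (_HI, _LO, _LO)),
            Shape("star", {"center": (22, 64), "radius": 12, "rotation": 0.2},
                  (_LO, _HI, _LO)),
            Shape("rectangle", {"top_left": (10, 96), "height": 20, "width": 22},
                  (_LO, _LO, _HI)),
            Shape("rectangle", {"top_left": (52, 12), "height": 22, "width": 22},
                  (_LO, _HI, _LO)),
            Shape("circle", {"center": (64, 64), "radius": 13}, (_LO, _LO, _HI)),
            Shape("star", {"center": (62, 106), "radius": 13, "rotation": 0.5},
                  (_HI, _LO, _LO)),
            Shape("star", {"center": (100, 24), "radius": 13, "rotation": 0.9},
                  (_LO, _LO, _HI)),
            Shape("circle", {"center": (102, 64), "radius": 11}, (_LO, _HI, _LO)),
            Shape("rectangle", {"top_left": (92, 96), "height": 24, "width": 24},
                  (_HI, _LO, _LO)),
        ),
        name="fig6",
    )


def _three_color() -> SceneSpec:
    """Several shapes in three object colors on a dark background."""
    return SceneSpec(
        size=(128, 128),
        background=(_LO, _LO, _LO),
        shapes=(
            Shape("circle", {"center": (22, 24), "radius": 12}, (_HI, _HI, _LO)),
            Shape("rectangle", {"top_left": (12, 76), "height": 24, "width": 26},
                  (_HI, _LO, _HI)),
            Shape("star", {"center": (64, 40), "radius": 14, "rotation": 0.4},
                  (_LO, _HI, _HI)),
            Shape("circle", {"center": (66, 92), "radius": 12}, (_HI, _HI, _LO)),
            Shape("rectangle", {"top_left": (94, 18), "height": 22, "width": 24},
                  (_LO, _HI, _HI)),
            Shape("star", {"center": (102, 84), "radius": 14, "rotation": 0.1},
                  (_HI, _LO, _HI)),
        ),
        name="fig7",
    )


def _many_objects() -> SceneSpec:
    """Many white objects on dark for the severe-noise study.

    White on dark so every channel carries the same strong signal; severe
    noise is then a per-channel robustness test rather than a color test.
    """
    return SceneSpec(
        size=(128, 128),
        background=(_LO, _LO, _LO),
        shapes=(
            Shape("circle", {"center": (22, 24), "radius": 12}, (_HI, _HI, _HI)),
            Shape("rectangle", {"top_left": (10, 70), "height": 24, "width": 28},
                  (_HI, _HI, _HI)),
            Shape("star", {"center": (64, 36), "radius": 15, "rotation": 0.3},
                  (_HI, _HI, _HI)),
            Shape("circle", {"center": (62, 92), "radius": 13}, (_HI, _HI, _HI)),
            Shape("rectangle", {"top_left": (94, 14), "height": 22, "width": 26},
                  (_HI, _HI, _HI)),
            Shape("circle", {"center": (102, 86), "radius": 14}, (_HI, _HI, _HI)),
        ),
        name="fig9",
    )


def _radius_study() -> SceneSpec:
    """A disk and a star for the localization-radius sweep."""
    return SceneSpec(
        size=(128, 128),
        background=(_LO, _LO, _LO),
        shapes=(
            Shape("circle", {"center": (40, 40), "radius": 22}, (_HI, _HI, _HI)),
            Shape(
                "star", {"center": (86, 84), "radius": 30, "rotation": 0.2},
                (_HI, _HI, _HI),
            ),
        ),
        name="fig11",
    )


def _equal_mean_pair() -> SceneSpec:
    """Two disks with identical channel-mean gray value but different colors."""
    return SceneSpec(
        size=(128, 128),
        background=(0.9, 0.9, 0.9),
        shapes=(
            Shape("circle", {"center": (44, 40), "radius": 20}, (0.9, 0.1, 0.1)),
            Shape("circle", {"center": (84, 88), "radius": 20}, (0.1, 0.9, 0.1)),
        ),
        name="equal_mean",
    )


SCENES = {
    "fig3": _three_disks,
    "fig6": _four_color_shapes,
    "fig7": _three_color,
    "fig9": _many_objects,
    "fig11": _radius_study,
    "equal_mean": _equal_mean_pair,
}


def scene(name: str) -> SceneSpec:
    """Look up a bundled demonstration scene by name."""
    try:
        return SCENES[name]()
    except KeyError:
        raise InvalidSpecError(
            f"unknown scene {name!r}; available: {sorted(SCENES)}"
        ) from None
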