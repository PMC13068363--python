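"""Stochastic recursive branching generator for dendritic morphologies.

Grows a k-ary segment tree in which each child deviates from its parent's
direction by a base branch angle plus uniform jitter, and shrinks by a
per-level length factor drawn uniformly from a decay band.  Rasterised trees
serve as controllable fixtures for the morphometrics pipeline: deeper
recursion produces denser, more space-filling structures with higher
box-counting dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FractalModelParams", "SegmentTree", "grow_tree", "rasterize"]


@dataclass(frozen=True)
class FractalModelParams:
    """Branching-model parameters.

    ``angle_jitter_deg`` (default ±12°) and the length-decay band
    (default 0.68–0.82 per level) are the stochastic perturbations; the base
    half-angle and trunk length are declared defaults of the generator.
    """

    depth: int = 8
    branch_angle_deg: float = 25.0
    angle_jitter_deg: float = 12.0
    length_decay_min: float = 0.68
    length_decay_max: float = 0.82
    trunk_length_px: float = 100.0
    branches_per_node: int = 2
    taper_frac: float = 0.3  # segment width as a fraction of its length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 < self.length_decay_min <= self.length_decay_max < 1.0):
            raise ValueError("need 0 < decay_min <= decay_max < 1")
        if self.angle_jitter_deg < 0:
            raise ValueError("jitter must be nonnegative")
        if self.branches_per_node < 1:
            raise ValueError("branches_per_node must be >= 1")
        if self.trunk_length_px <= 0:
            raise ValueError("trunk_length_px must be positive")


@dataclass
class SegmentTree:
    """Flat list of line segments (x0, y0, x1, y1, level, width_px)."""

    segments: list[tuple[float, float, float, float, int, float]]

    def __len__(self) -> int:
        return len(self.segments)

    def bounding_box(self) -> tuple[float, float, float, float]:
        xs = [s[0] for s in self.segments] + [s[2] for s in self.segments]
        ys = [s[1] for s in self.segments] + [s[3] for s in self.segments]
        return min(xs), min(ys), max(xs), max(ys)


def grow_tree(params: FractalModelParams) -> SegmentTree:
    """Grow the recursive branching tree; deterministic for a fixed seed.

    The trunk points "up" (+y).  At each node the i-th of k children turns by
    a symmetric multiple of the base branch angle plus U(-jitter, +jitter),
    and its length is the parent's times U(decay_min, decay_max).  A full
    k-ary tree of depth d has (k^(d+1) - 1)/(k - 1) segments.
    """
    rng = np.random.default_rng(params.seed)
    k = params.branches_per_node
    # symmetric angular offsets for k children, in units of the base angle
    if k == 1:
        offsets = [0.0]
    else:
        offsets = [(-1.0 + 2.0 * i / (k - 1)) for i in range(k)]

    segments: list[tuple[float, float, float, float, int, float]] = []
    # stack of (x, y, direction_rad, length, level)
    stack = [(0.0, 0.0, math.pi / 2.0, params.trunk_length_px, 0)]
    while stack:
        x, y, direction, length, level = stack.pop()
        x1 = x + length * math.cos(direction)
        y1 = y + length * math.sin(direction)
        # dendrite-like taper: width proportional to segment length
        width = params.taper_frac * length
        segments.append((x, y, x1, y1, level, width))
        if level >= params.depth:
            continue
        for off in reversed(offsets):
            jitter = (
                rng.uniform(-params.angle_jitter_deg, params.angle_jitter_deg)
                if params.angle_jitter_deg > 0
                else 0.0
            )
            child_dir = direction + math.radians(
                off * params.branch_angle_deg + jitter
            )
            decay = (
                params.length_decay_min
                if params.length_decay_min == params.length_decay_max
                else rng.uniform(params.length_decay_min, params.length_decay_max)
            )
            stack.append((x1, y1, child_dir, length * decay, level + 1))
    return SegmentTree(segments)


def _draw_segment(mask: np.ndarray, x0: float, y0: float, x1: float, y1: float
                  ) -> None:
    """Integer midpoint-stepping rasterisation of a 1-px segment."""
    h, w = mask.shape
    n = int(max(abs(x1 - x0), abs(y1 - y0))) + 1
    xs = np.rint(np.linspace(x0, x1, n)).astype(int)
    ys = np.rint(np.linspace(y0, y1, n)).astype(int)
    mask[np.clip(ys, 0, h - 1), np.clip(xs, 0, w - 1)] = True


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def rasterize(
    tree: SegmentTree,
    image_size_px: tuple[int, int] = (1024, 1024),
    stroke_from_width: bool = False,
) -> np.ndarray:
    """Rasterise a segment tree to a boolean foreground mask.

    The tree bounding box is scaled isotropically to fit the image with a 5%
    margin.  Lines are drawn by integer midpoint stepping with no
    anti-aliasing; stroke width is 1 px unless ``stroke_from_width`` maps the
    per-segment width (in tree units) through the image scale and
    ``max(1, round(.))``.  The y axis is flipped so the trunk grows from the
    bottom of the image.
    """
    if len(tree) == 0:
        raise ValueError("empty tree")
    h, w = image_size_px
    if min(h, w) < 64:
        raise ValueError("image too small (< 64 px)")
    x_min, y_min, x_max, y_max = tree.bounding_box()
    span_x = max(x_max - x_min, 1e-9)
    span_y = max(y_max - y_min, 1e-9)
    margin = 0.05
    scale = min(w * (1 - 2 * margin) / span_x, h * (1 - 2 * margin) / span_y)
    off_x = (w - scale * span_x) / 2.0
    off_y = (h - scale * span_y) / 2.0

    from scipy import ndimage

    # draw 1-px centrelines grouped by stroke width, then thicken each group
    # by a disk of the matching radius (round caps and joins)
    by_stroke: dict[int, list] = {}
    for x0, y0, x1, y1, _level, width in tree.segments:
        px0 = off_x + scale * (x0 - x_min)
        px1 = off_x + scale * (x1 - x_min)
        # flip y: image row 0 is the top
        py0 = h - 1 - (off_y + scale * (y0 - y_min))
        py1 = h - 1 - (off_y + scale * (y1 - y_min))
        if stroke_from_width:
            # quantise to powers of two so thickening needs few passes
            stroke = max(1, int(2 ** round(math.log2(max(width * scale, 1.0)))))
        else:
            stroke = 1
        by_stroke.setdefault(stroke, []).append((px0, py0, px1, py1))

    mask = np.zeros((h, w), dtype=bool)
    for stroke, segs in by_stroke.items():
        layer = np.zeros((h, w), dtype=bool)
        for px0, py0, px1, py1 in segs:
            _draw_segment(layer, px0, py0, px1, py1)
        if stroke > 1:
            # thicken via the Euclidean distance to the centreline,
            # restricted to the layer's padded bounding box
            ys, xs = np.nonzero(layer)
            pad = stroke // 2 + 1
            y0b, y1b = max(ys.min() - pad, 0), min(ys.max() + pad + 1, h)
            x0b, x1b = max(xs.min() - pad, 0), min(xs.max() + pad + 1, w)
            sub = layer[y0b:y1b, x0b:x1b]
            dist = ndimage.distance_transform_edt(~sub)
            layer = np.zeros_like(layer)
            layer[y0b:y1b, x0b:x1b] = dist <= stroke / 2.0
        mask |= layer
    return mask
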