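"""Image morphometrics: segmentation, fractal dimension, branching, lacunarity.

Operates on 2-D boolean foreground masks (row-major, origin top-left).
Otsu segmentation and topology-preserving skeletonisation come from
scikit-image; the box-counting dimension, the gliding-box lacunarity, and
the branch/end-point and node-degree accounting are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "FractalFit",
    "BranchReport",
    "LacunarityReport",
    "segment_otsu",
    "box_count_dimension",
    "default_box_sizes",
    "skeleton_branch_metrics",
    "gliding_box_lacunarity",
]


@dataclass
class FractalFit:
    d_f: float
    r_squared: float
    box_sizes: np.ndarray
    counts: np.ndarray


@dataclass
class BranchReport:
    branch_points: int
    end_points: int
    branch_pixels: int  # total skeleton pixels
    branching_ratio: float
    node_degrees: dict[int, int]
    mean_node_degree: float


@dataclass
class LacunarityReport:
    per_size: list[tuple[int, float]]
    mean_lacunarity: float
    range: tuple[float, float]
    definition: str = "cv2"


def segment_otsu(image: np.ndarray, invert: bool = False) -> np.ndarray:
    """Binarise a grayscale image by Otsu's between-class-variance criterion.

    Foreground is the brighter class; pass ``invert=True`` when the
    structures of interest are dark on a bright background.  A constant
    image has no separable classes and raises.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.all(image == image.flat[0]):
        raise ValueError("constant image: no threshold separates two classes")
    thr = threshold_otsu(image, nbins=256)
    mask = image > thr
    return ~mask if invert else mask


def default_box_sizes(shape: tuple[int, int], n_sizes: int = 12,
                      max_size: int = 4096) -> np.ndarray:
    """Power-of-two box sizes from 2 px up to min(image extent, max_size)."""
    limit = min(min(shape), max_size)
    sizes = []
    s = 2
    while s <= limit and len(sizes) < n_sizes:
        sizes.append(s)
        s *= 2
    return np.asarray(sizes, dtype=int)


def _occupied_boxes(mask: np.ndarray, size: int) -> int:
    """Count boxes of an origin-anchored size x size grid touching foreground.

    Partial boxes at the right/bottom edges are included.
    """
    h, w = mask.shape
    nh = -(-h // size)
    nw = -(-w // size)
    padded = np.zeros((nh * size, nw * size), dtype=bool)
    padded[:h, :w] = mask
    blocks = padded.reshape(nh, size, nw, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_dimension(
    mask: np.ndarray, box_sizes: np.ndarray | None = None
) -> FractalFit:
    """Box-counting fractal dimension of a binary mask.

    For each box size s, foreground-occupied cells of the origin-anchored
    s x s grid are counted; D_f is minus the slope of the least-squares line
    of ln(count) against ln(s), and the R^2 of that line is reported with it.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if box_sizes is None:
        box_sizes = default_box_sizes(mask.shape)
    box_sizes = np.asarray(box_sizes, dtype=int)
    if box_sizes.size < 3:
        raise ValueError("need at least 3 box sizes")
    if np.any(box_sizes < 2):
        raise ValueError("box sizes must be >= 2 px")
    counts = np.array([_occupied_boxes(mask, int(s)) for s in box_sizes])
    ln_s = np.log(box_sizes.astype(float))
    ln_n = np.log(counts.astype(float))
    slope, intercept = np.polyfit(ln_s, ln_n, 1)
    fit = slope * ln_s + intercept
    ss_res = float(np.sum((ln_n - fit) ** 2))
    ss_tot = float(np.sum((ln_n - ln_n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractalFit(float(-slope), r2, box_sizes, counts)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_branch_metrics(mask: np.ndarray) -> BranchReport:
    """Branching topology of the 1-px topology-preserving skeleton.

    A skeleton pixel with >= 3 eight-connected skeleton neighbours is a
    branch pixel; a pixel with exactly one neighbour is an end point.
    Adjacent branch pixels are merged (8-connected components) into single
    junction nodes before degree counting — raw per-pixel counting inflates
    the degree of thick junctions — and a merged node's degree is the number
    of distinct skeleton pixels adjacent to the cluster but outside it.
    The node-degree histogram pools junction nodes with degree-1 end points;
    the branching ratio is branch_points / end_points (0 when there are no
    end points).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = skeletonize(mask)
    nbrs = ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL,
                            mode="constant", cval=0)
    nbrs = np.where(skel, nbrs, 0)
    branch_mask = skel & (nbrs >= 3)
    end_mask = skel & (nbrs == 1)
    branch_points = int(branch_mask.sum())
    end_points = int(end_mask.sum())
    total_pixels = int(skel.sum())

    degrees: list[int] = []
    labels, n_clusters = ndimage.label(branch_mask,
                                       structure=np.ones((3, 3), dtype=int))
    for lab in range(1, n_clusters + 1):
        cluster = labels == lab
        dilated = ndimage.binary_dilation(cluster,
                                          structure=np.ones((3, 3), dtype=bool))
        degree = int((dilated & skel & ~cluster).sum())
        degrees.append(min(degree, 8))
    degrees.extend([1] * end_points)

    histogram: dict[int, int] = {}
    for d in degrees:
        histogram[d] = histogram.get(d, 0) + 1
    mean_degree = float(np.mean(degrees)) if degrees else 0.0
    ratio = branch_points / end_points if end_points > 0 else 0.0
    return BranchReport(
        branch_points=branch_points,
        end_points=end_points,
        branch_pixels=total_pixels,
        branching_ratio=ratio,
        node_degrees=histogram,
        mean_node_degree=mean_degree,
    )


def gliding_box_lacunarity(
    mask: np.ndarray, n_sizes: int = 25, definition: str = "cv2"
) -> LacunarityReport:
    """Gliding-box lacunarity across geometrically spaced box sizes.

    For each box size r (``n_sizes`` values geometrically spaced in
    [2, min(H, W)/2]) an r x r window glides at stride 1 and the foreground
    mass M in each placement is recorded.  Under the default ``cv2``
    definition Lambda(r) = var(M)/mean(M)^2 (zero for any uniform mask);
    ``allain_cloitre`` reports E[M^2]/E[M]^2 = 1 + var/mean^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask (mean box mass would be 0)")
    if definition not in ("cv2", "allain_cloitre"):
        raise ValueError(f"unknown lacunarity definition {definition!r}")
    h, w = mask.shape
    r_max = min(h, w) // 2
    if r_max < 2:
        raise ValueError("image too small: need min dimension >= 4")
    sizes = np.unique(
        np.rint(np.geomspace(2, r_max, n_sizes)).astype(int)
    )
    # integral image for O(1) box sums
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)

    per_size: list[tuple[int, float]] = []
    for r in sizes:
        sums = (
            integral[r:, r:]
            - integral[:-r, r:]
            - integral[r:, :-r]
            + integral[:-r, :-r]
        ).astype(float)
        mean = sums.mean()
        var = sums.var()
        lam = var / mean**2
        if definition == "allain_cloitre":
            lam += 1.0
        per_size.append((int(r), float(lam)))
    values = [v for _, v in per_size]
    return LacunarityReport(
        per_size=per_size,
        mean_lacunarity=float(np.mean(values)),
        range=(float(min(values)), float(max(values))),
        definition=definition,
    )
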