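"""Object masks from near-uniform-background images and the
radius-dependent interior/border split used by the region variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, SegmentationFailureError
from .lbp import _sample_membership, neighbor_offsets, to_gray
from .patterns import NeighborhoodSpec

_N_BINS = 256


def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximizing between-class variance of the 256-bin histogram.

    Intensities are min-max normalized onto the 256 bins; the returned
    threshold is on the original intensity scale.  Ties break toward
    the lower threshold.
    """
    img = to_gray(image)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise DegenerateInputError("constant image has no threshold")
    bins = np.minimum(
        ((img - lo) / (hi - lo) * _N_BINS).astype(np.int64), _N_BINS - 1
    )
    counts = np.bincount(bins.ravel(), minlength=_N_BINS).astype(np.float64)
    p = counts / counts.sum()
    centers = np.arange(_N_BINS) + 0.5

    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    # threshold candidate k separates bins <= k from bins > k
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -np.inf
    v = var_between[:-1]
    vmax = v.max()
    # ties (e.g. the plateau across an empty histogram gap) break toward
    # the lower threshold, robust to float rounding
    k = int(np.flatnonzero(v >= vmax - 1e-9 * abs(vmax))[0])
    # boundary between bin k and bin k+1, mapped back to intensity scale
    return lo + (k + 1) / _N_BINS * (hi - lo)


def leaf_mask(image: np.ndarray, darker: bool = True) -> np.ndarray:
    """Foreground mask: Otsu threshold, largest 8-connected component, holes filled.

    ``darker=True`` keeps pixels strictly below the threshold (object on
    light background); ``darker=False`` keeps pixels above it.
    """
    img = to_gray(image)
    t = otsu_threshold(img)
    fg = img < t if darker else img > t
    if not fg.any():
        raise SegmentationFailureError("no foreground pixels after thresholding")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise SegmentationFailureError("no connected component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    return ndimage.binary_fill_holes(mask)


@dataclass
class RegionPair:
    """Disjoint interior/border partition of a mask at one LBP radius."""

    interior: np.ndarray
    border: np.ndarray
    R: float


def region_split(mask: np.ndarray, spec: NeighborhoodSpec) -> RegionPair:
    """Split ``mask`` into interior and border at radius ``spec.R``.

    Border pixels have at least one of the P sample points outside the
    mask (the image frame counts as outside); interior pixels have all
    sample points inside.  Membership of an off-grid sample point
    requires every pixel in its bilinear support to be a mask pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    all_inside = np.ones_like(mask)
    for dr, dc in neighbor_offsets(spec):
        all_inside &= _sample_membership(mask, dr, dc)
    interior = mask & all_inside
    border = mask & ~all_inside
    return RegionPair(interior=interior, border=border, R=spec.R)
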