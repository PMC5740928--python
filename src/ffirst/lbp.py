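"""Gaussian scale stack and per-pixel sign/magnitude LBP code images.

Sampling convention: neighbor p sits at angle ``2*pi*p/P`` from the
center, neighbor 0 due east, angles counter-clockwise (i.e. column
offset ``+R*cos``, row offset ``-R*sin``).  Off-grid samples use
bilinear interpolation; offsets within 1e-9 of an integer are snapped
so that axis-aligned samples are read exactly, which makes 90-degree
rotation equivariance exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InvalidParameterError
from .patterns import NeighborhoodSpec

#: Gaussian filtering is skipped below this sigma (kernel ~ identity).
SIGMA_CUTOFF = 0.3

#: ITU-R BT.601 luminance weights for RGB conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_SNAP_TOL = 1e-9
_MEMBERSHIP_TOL = 1e-9


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an 8/16-bit or float, gray or RGB(A) image to float64 luminance."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise DegenerateInputError("image contains non-finite values")
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise DegenerateInputError("image must be 2D and at least 3x3")
    return arr


def neighbor_offsets(spec: NeighborhoodSpec) -> np.ndarray:
    """(P, 2) array of (row, col) offsets of the P samples, snapped to grid."""
    p = np.arange(spec.P)
    ang = 2.0 * np.pi * p / spec.P
    dc = spec.R * np.cos(ang)
    dr = -spec.R * np.sin(ang)
    offs = np.stack([dr, dc], axis=1)
    snapped = np.round(offs)
    close = np.abs(offs - snapped) < _SNAP_TOL
    offs[close] = snapped[close]
    return offs


def effective_radius(spec: NeighborhoodSpec) -> float:
    """Radius r = R*sin(pi/P) of the effective area around each sample."""
    return spec.R * np.sin(np.pi / spec.P)


def sigma_for_radius(spec: NeighborhoodSpec) -> float:
    """Gaussian sigma for a scale level: half the effective radius.

    With sigma = r/2 roughly 95% of the kernel mass falls inside the
    effective area of radius r.
    """
    return effective_radius(spec) / 2.0


@dataclass
class ScaleLevel:
    index: int  # 1-based
    R: float
    r: float
    sigma: float
    image: np.ndarray


@dataclass
class ScaleStack:
    levels: list[ScaleLevel]

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> ScaleLevel:
        return self.levels[i]


def radii_schedule(n_scales: int, P: int = 8, R1: float = 1.0) -> list[tuple[float, float, float]]:
    """Radius schedule [(R_i, r_i, sigma_i)]: R_1 = 1, R_i = R_{i-1}*sqrt(2)."""
    if n_scales < 1:
        raise InvalidParameterError("n_scales must be >= 1")
    out = []
    for i in range(n_scales):
        R = R1 * (np.sqrt(2.0) ** i)
        spec = NeighborhoodSpec(P=P, R=R)
        out.append((R, effective_radius(spec), sigma_for_radius(spec)))
    return out


def build_scale_stack(image: np.ndarray, spec: NeighborhoodSpec, n_scales: int) -> ScaleStack:
    """Gaussian-filter ``image`` once per scale of the sqrt(2) radius schedule."""
    img = to_gray(image)
    schedule = radii_schedule(n_scales, P=spec.P, R1=spec.R)
    R_max = schedule[-1][0]
    if min(img.shape) <= 2 * R_max:
        raise DegenerateInputError(
            f"image {img.shape} too small for coarsest radius R={R_max:.2f}"
        )
    levels = []
    for i, (R, r, sigma) in enumerate(schedule, start=1):
        if sigma < SIGMA_CUTOFF:
            filtered = img.copy()
        else:
            filtered = ndimage.gaussian_filter(img, sigma, mode="reflect")
        levels.append(ScaleLevel(index=i, R=R, r=r, sigma=sigma, image=filtered))
    return ScaleStack(levels)


@dataclass
class CodeImage:
    """Per-pixel LBP codes plus a validity mask (invalid pixels carry no code)."""

    codes: np.ndarray  # int32, shape of image
    valid: np.ndarray  # bool, shape of image
    P: int

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def empty(self) -> bool:
        return self.n_valid == 0


@dataclass
class MagnitudeThresholds:
    """Per-neighbor mean absolute difference t_p, pooled over m valid pixels."""

    t: np.ndarray  # shape (P,)
    m: int


def _shifted(level: np.ndarray, dr: float, dc: float) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample of ``level`` at every pixel offset by (dr, dc).

    Returns (values, inside) where ``inside`` is True when all bilinear
    support pixels lie inside the image frame.  Outside samples read 0.
    """
    H, W = level.shape
    rows, cols = np.indices(level.shape, dtype=np.float64)
    rs, cs = rows + dr, cols + dc
    r0 = np.floor(rs)
    c0 = np.floor(cs)
    fr = rs - r0
    fc = cs - c0
    r0 = r0.astype(np.int64)
    c0 = c0.astype(np.int64)

    inside = np.ones(level.shape, dtype=bool)
    corners = {}
    for (ro, used) in ((0, True), (1, fr > 0)):
        for (co, usedc) in ((0, True), (1, fc > 0)):
            rr = r0 + ro
            cc = c0 + co
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            inside &= ok | ~(np.asarray(used) & np.asarray(usedc))
            corners[(ro, co)] = level[np.clip(rr, 0, H - 1), np.clip(cc, 0, W - 1)]
    a, b = corners[(0, 0)], corners[(0, 1)]
    c, d = corners[(1, 0)], corners[(1, 1)]
    # difference form: exact on constant and linear images
    vals = a + fr * (c - a) + fc * (b - a) + (fr * fc) * (a + d - b - c)
    vals = np.where(inside, vals, 0.0)
    return vals, inside


def _sample_membership(mask: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """True where the sample point at offset (dr, dc) lies inside ``mask``.

    A continuous point belongs to the region iff every pixel with
    nonzero bilinear weight is a mask pixel; the image frame counts as
    outside.
    """
    vals, inside = _shifted(mask.astype(np.float64), dr, dc)
    return inside & (vals >= 1.0 - _MEMBERSHIP_TOL)


def sample_circle(level: np.ndarray, x: float, y: float, spec: NeighborhoodSpec) -> np.ndarray:
    """Bilinear samples of the P circle points around (x, y) = (col, row)."""
    H, W = level.shape
    offs = neighbor_offsets(spec)
    out = np.empty(spec.P)
    for p, (dr, dc) in enumerate(offs):
        rs, cs = y + dr, x + dc
        if not (0 <= rs <= H - 1 and 0 <= cs <= W - 1):
            raise InvalidParameterError(f"sample point {p} outside image bounds")
        r0, c0 = int(np.floor(rs)), int(np.floor(cs))
        fr, fc = rs - r0, cs - c0
        r1, c1 = min(r0 + 1, H - 1), min(c0 + 1, W - 1)
        a, b = level[r0, c0], level[r0, c1]
        c, d = level[r1, c0], level[r1, c1]
        out[p] = a + fr * (c - a) + fc * (b - a) + (fr * fc) * (a + d - b - c)
    return out


def _neighbor_stack(
    level: np.ndarray,
    spec: NeighborhoodSpec,
    centers: np.ndarray,
    sample_region: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor values (P, H, W) and the per-pixel validity mask.

    ``centers`` selects which pixels get a code; a center is valid when
    all P sample points lie inside ``sample_region`` (whole frame when
    None).  The frame always counts as outside.
    """
    offs = neighbor_offsets(spec)
    vals = np.empty((spec.P,) + level.shape)
    valid = centers.copy()
    for p, (dr, dc) in enumerate(offs):
        v, inside = _shifted(level, dr, dc)
        vals[p] = v
        if sample_region is None:
            valid &= inside
        else:
            valid &= _sample_membership(sample_region, dr, dc)
    return vals, valid


def sign_lbp_image(
    level: np.ndarray,
    spec: NeighborhoodSpec,
    centers: np.ndarray,
    sample_region: np.ndarray | None = None,
) -> CodeImage:
    """Sign-LBP codes: bit p set iff f(x,y) - f(x_p,y_p) <= 0."""
    vals, valid = _neighbor_stack(level, spec, centers, sample_region)
    codes = np.zeros(level.shape, dtype=np.int32)
    for p in range(spec.P):
        codes |= ((level - vals[p] <= 0).astype(np.int32)) << p
    codes[~valid] = 0
    return CodeImage(codes=codes, valid=valid, P=spec.P)


def magnitude_thresholds(
    level: np.ndarray,
    spec: NeighborhoodSpec,
    centers: np.ndarray,
    sample_region: np.ndarray | None = None,
) -> MagnitudeThresholds:
    """Per-neighbor mean absolute difference over all valid pixels."""
    vals, valid = _neighbor_stack(level, spec, centers, sample_region)
    m = int(valid.sum())
    if m == 0:
        raise DegenerateInputError("no valid pixels for magnitude thresholds")
    t = np.array([np.abs(level - vals[p])[valid].mean() for p in range(spec.P)])
    return MagnitudeThresholds(t=t, m=m)


def lbp_pair(
    level: np.ndarray,
    spec: NeighborhoodSpec,
    centers: np.ndarray,
    sample_region: np.ndarray | None = None,
) -> tuple[CodeImage, CodeImage, MagnitudeThresholds]:
    """Sign and magnitude code images sharing one neighbor-sampling pass."""
    vals, valid = _neighbor_stack(level, spec, centers, sample_region)
    sign_codes = np.zeros(level.shape, dtype=np.int32)
    mag_codes = np.zeros(level.shape, dtype=np.int32)
    m = int(valid.sum())
    t = np.zeros(spec.P)
    for p in range(spec.P):
        diff = level - vals[p]
        sign_codes |= ((diff <= 0).astype(np.int32)) << p
        adiff = np.abs(diff)
        if m > 0:
            t[p] = adiff[valid].mean()
        mag_codes |= ((adiff - t[p] <= 0).astype(np.int32)) << p
    sign_codes[~valid] = 0
    mag_codes[~valid] = 0
    return (
        CodeImage(codes=sign_codes, valid=valid, P=spec.P),
        CodeImage(codes=mag_codes, valid=valid, P=spec.P),
        MagnitudeThresholds(t=t, m=max(m, 1)),
    )


def magnitude_lbp_image(
    level: np.ndarray,
    spec: NeighborhoodSpec,
    thresholds: MagnitudeThresholds,
    centers: np.ndarray,
    sample_region: np.ndarray | None = None,
) -> CodeImage:
    """Magnitude-LBP codes: bit p set iff |f(x,y) - f(x_p,y_p)| - t_p <= 0."""
    vals, valid = _neighbor_stack(level, spec, centers, sample_region)
    codes = np.zeros(level.shape, dtype=np.int32)
    for p in range(spec.P):
        codes |= ((np.abs(level - vals[p]) - thresholds.t[p] <= 0).astype(np.int32)) << p
    codes[~valid] = 0
    return CodeImage(codes=codes, valid=valid, P=spec.P)
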