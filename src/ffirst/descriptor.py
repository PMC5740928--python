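"""Assembly of per-scale HF features into sliding multi-scale descriptors.

A stack of S scales (radius step sqrt(2), R_1 = 1) yields S per-scale
feature vectors; windows of c adjacent scales are concatenated into
``n_conc = S - c + 1`` descriptors per image region, providing a family
of descriptors shifted in scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features, lbp
from .errors import InvalidParameterError
from .patterns import NeighborhoodSpec, OrbitTable, enumerate_orbits
from .segmentation import region_split

VARIANTS = ("all", "interior", "border")


@dataclass(frozen=True)
class MultiScaleConfig:
    """Descriptor configuration; defaults give radii 1 .. 11.31 (S=8)."""

    P: int = 8
    n_scales: int = 8
    window: int = 5
    mode: str = "full"  # "full" | "uniform"
    plus: bool = True
    R1: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.n_scales < self.window:
            raise InvalidParameterError("need 1 <= window <= n_scales")
        if self.mode not in ("full", "uniform"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")

    @property
    def n_conc(self) -> int:
        return self.n_scales - self.window + 1

    def fingerprint(self) -> dict:
        return {
            "P": self.P,
            "n_scales": self.n_scales,
            "window": self.window,
            "mode": self.mode,
            "plus": self.plus,
            "R1": self.R1,
        }


def radii_schedule(config: MultiScaleConfig) -> list[tuple[float, float, float]]:
    """[(R_i, r_i, sigma_i)] for i = 1..S with R_i = R_{i-1} * sqrt(2)."""
    return lbp.radii_schedule(config.n_scales, P=config.P, R1=config.R1)


@dataclass
class FfirstDescriptor:
    """n_conc multi-scale vectors for one image region.

    Each window vector concatenates ``window`` consecutive per-scale
    descriptors (finest to coarsest, step 1) and is L1-normalized.
    Windows whose every scale saw an empty region are flagged empty and
    zeroed.
    """

    windows: np.ndarray  # (n_conc, window * per_scale_dim)
    empty: np.ndarray  # (n_conc,) bool
    variant: str
    config: MultiScaleConfig = field(repr=False)

    @property
    def n_conc(self) -> int:
        return self.windows.shape[0]

    @property
    def all_empty(self) -> bool:
        return bool(self.empty.all())


def sliding_concat(
    per_scale: list[features.ScaleDescriptor], c: int
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate windows of c adjacent scales; returns (vectors, empty flags)."""
    S = len(per_scale)
    if S < c or c < 1:
        raise InvalidParameterError(f"need 1 <= c <= n_scales, got c={c}, S={S}")
    vectors = []
    empties = []
    for j in range(S - c + 1):
        block = per_scale[j : j + c]
        vectors.append(np.concatenate([sd.values for sd in block]))
        empties.append(all(sd.empty for sd in block))
    return np.stack(vectors), np.asarray(empties, dtype=bool)


def _l1_normalize(v: np.ndarray) -> np.ndarray:
    s = np.abs(v).sum()
    return v / s if s > 0 else v


def extract_ffirst(
    image: np.ndarray,
    mask: np.ndarray | None,
    config: MultiScaleConfig,
    variant: str = "all",
    table: OrbitTable | None = None,
) -> FfirstDescriptor:
    """Compute the multi-scale descriptor of one image region.

    ``variant`` selects which mask pixels are described at each scale:
    ``all`` mask pixels, the ``interior`` (all P samples inside the
    mask), or the ``border`` (at least one sample outside).  Sample
    values are read from the full filtered image; validity only
    requires samples to stay inside the image frame (interior centers
    satisfy the stronger in-mask condition by construction).
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"variant must be one of {VARIANTS}")
    if table is None:
        table = enumerate_orbits(config.P)
    img = lbp.to_gray(image)
    if mask is None:
        if variant != "all":
            raise InvalidParameterError(f"variant {variant!r} requires a mask")
        mask = np.ones(img.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise InvalidParameterError("mask shape must match image shape")

    base_spec = NeighborhoodSpec(P=config.P, R=config.R1)
    stack = lbp.build_scale_stack(img, base_spec, config.n_scales)
    per_scale = []
    for level in stack:
        spec = NeighborhoodSpec(P=config.P, R=level.R)
        if variant == "all":
            centers = mask
        else:
            pair = region_split(mask, spec)
            centers = pair.interior if variant == "interior" else pair.border
        sign_ci, mag_ci, _ = lbp.lbp_pair(level.image, spec, centers)
        per_scale.append(
            features.scale_descriptor(
                sign_ci,
                mag_ci,
                table,
                mode=config.mode,
                plus=config.plus,
                scale_index=level.index,
            )
        )
    windows, empty = sliding_concat(per_scale, config.window)
    windows = np.stack([_l1_normalize(w) for w in windows])
    windows[empty] = 0.0
    return FfirstDescriptor(windows=windows, empty=empty, variant=variant, config=config)
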