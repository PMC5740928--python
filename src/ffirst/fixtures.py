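"""Deterministic synthetic textures and leaf-like objects for testing.

Texture classes are isotropic band-pass-filtered noise.  Because the
descriptor under test is rotation-invariant, classes must differ in
radial frequency content, never in orientation.  To stay separable
under the rescaling applied during augmentation, the default class
family encodes identity in the *ratio* between two narrow frequency
bands, which is invariant to image scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError

_NYQUIST = 0.5


@dataclass(frozen=True)
class TextureSpec:
    """Isotropic band-pass noise: bands = [(center_freq, bandwidth, weight)]."""

    class_id: int
    bands: tuple[tuple[float, float, float], ...]
    contrast: float = 0.18
    base_level: float = 0.5

    def __post_init__(self) -> None:
        if not self.bands:
            raise InvalidParameterError("at least one frequency band required")
        for f, bw, w in self.bands:
            if not (0 < f < _NYQUIST) or bw <= 0 or w <= 0:
                raise InvalidParameterError(f"bad band ({f}, {bw}, {w})")

    def max_frequency(self) -> float:
        return max(f + 2 * bw for f, bw, _ in self.bands)


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def bandpass_noise(spec: TextureSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance isotropic noise with the spec's radial spectrum."""
    noise = rng.standard_normal((size, size))
    F = np.fft.fft2(noise)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    rad = np.hypot(fy, fx)
    gain = np.zeros_like(rad)
    for f, bw, w in spec.bands:
        gain += w * np.exp(-0.5 * ((rad - f) / bw) ** 2)
    tex = np.fft.ifft2(F * gain).real
    std = tex.std()
    if std == 0:
        raise InvalidParameterError("degenerate band produced a constant texture")
    return (tex - tex.mean()) / std


def texture_instance(
    spec: TextureSpec,
    size: int,
    seed: int,
    index: int,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
) -> np.ndarray:
    """One texture image: band-pass noise, rotated and rescaled, center crop.

    Same (spec, seed, index) yields a bit-identical image.
    """
    if spec.max_frequency() / min(scale, 1.0) >= _NYQUIST:
        raise InvalidParameterError("band exceeds Nyquist after scaling")
    rng = _rng_for(seed, spec.class_id, index)
    margin = 1.5  # rotation head-room
    base = int(np.ceil(size * margin / min(scale, 1.0)))
    tex = bandpass_noise(spec, base, rng)
    if rotation_deg:
        tex = ndimage.rotate(tex, rotation_deg, reshape=False, order=3, mode="reflect")
    if scale != 1.0:
        tex = ndimage.zoom(tex, scale, order=3, mode="reflect")
    h, w = tex.shape
    r0, c0 = (h - size) // 2, (w - size) // 2
    tex = tex[r0 : r0 + size, c0 : c0 + size]
    img = spec.base_level + spec.contrast * tex
    return np.clip(img, 0.0, 1.0)


#: Canonical class signatures as (frequency ratio, weight) band lists on a
#: shared base frequency.  Identity is carried by scale-invariant
#: attributes only — band count, band frequency ratios and relative band
#: weights — so classes stay separable when instances are rescaled.
_CLASS_FAMILIES: tuple[tuple[tuple[float, float], ...], ...] = (
    ((1.0, 1.0),),
    ((1.0, 1.0), (1.8, 1.0)),
    ((1.0, 1.0), (2.7, 1.0)),
    ((1.0, 1.0), (4.0, 1.0)),
    ((1.0, 1.0), (6.0, 1.0)),
    ((1.0, 1.0), (1.8, 0.9), (3.24, 0.8)),
    ((1.0, 1.0), (2.4, 0.9), (5.76, 0.7)),
    ((1.0, 0.25), (1.8, 1.0)),
    ((1.0, 0.25), (4.0, 1.0)),
    ((1.0, 1.0), (1.8, 0.85), (3.24, 0.7), (5.83, 0.6)),
)


def default_texture_specs(n_classes: int, f0: float = 0.05) -> list[TextureSpec]:
    """Texture classes separable under rescaling (up to 10 distinct)."""
    if n_classes < 2:
        raise InvalidParameterError("need at least 2 classes")
    if n_classes > len(_CLASS_FAMILIES):
        raise InvalidParameterError(
            f"at most {len(_CLASS_FAMILIES)} default classes are defined"
        )
    specs = []
    for k in range(n_classes):
        bands = tuple(
            (f0 * r, 0.12 * f0 * r, w) for r, w in _CLASS_FAMILIES[k]
        )
        specs.append(TextureSpec(class_id=k, bands=bands))
    return specs


def gen_texture_dataset(
    n_classes: int,
    n_per_class: int,
    seed: int = 0,
    size: int = 64,
    rotation_range: tuple[float, float] = (0.0, 0.0),
    scale_range: tuple[float, float] = (1.0, 1.0),
    specs: list[TextureSpec] | None = None,
) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Class-structured texture images with controlled rotation/scale.

    Returns (images, labels, provenance) where provenance records the
    rotation, scale and seed of every instance.
    """
    if n_classes < 2:
        raise InvalidParameterError("need at least 2 classes")
    if specs is None:
        specs = default_texture_specs(n_classes)
    if len(specs) != n_classes:
        raise InvalidParameterError("len(specs) must equal n_classes")
    images, labels, rows = [], [], []
    for spec in specs:
        for i in range(n_per_class):
            rng = _rng_for(seed, spec.class_id, i, 1)  # augmentation stream
            rot = float(rng.uniform(*rotation_range))
            sc = float(rng.uniform(*scale_range))
            img = texture_instance(spec, size, seed, i, rotation_deg=rot, scale=sc)
            images.append(img)
            labels.append(spec.class_id)
            rows.append(
                {
                    "class": spec.class_id,
                    "instance": i,
                    "rotation_deg": rot,
                    "scale": sc,
                    "seed": seed,
                }
            )
    return images, np.asarray(labels), pd.DataFrame(rows)


@dataclass(frozen=True)
class LeafSpec:
    """Leaf-like dark object on a near-white background."""

    class_id: int
    axes: tuple[float, float] = (0.34, 0.22)  # semi-axes, fraction of image size
    serration_amp: float = 0.04
    serration_freq: int = 12
    interior: TextureSpec | None = None
    border: TextureSpec | None = None
    border_width: float = 5.0
    background: float = 0.92
    object_level: float = 0.38
    contrast: float = 0.10

    def __post_init__(self) -> None:
        if min(self.axes) <= 0.02:
            raise InvalidParameterError("degenerate leaf axes")
        if self.object_level + self.contrast >= self.background - 0.1:
            raise InvalidParameterError("object must be strictly darker than background")


def leaf_instance(
    spec: LeafSpec, size: int, seed: int, index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Render one leaf image and its ground-truth mask."""
    rng = _rng_for(seed, 1000 + spec.class_id, index)
    cy = cx = (size - 1) / 2.0
    yy, xx = np.indices((size, size), dtype=np.float64)
    theta0 = rng.uniform(0, 2 * np.pi)  # leaf orientation
    phase = rng.uniform(0, 2 * np.pi)
    a = spec.axes[0] * size * rng.uniform(0.95, 1.05)
    b = spec.axes[1] * size * rng.uniform(0.95, 1.05)
    dy, dx = yy - cy, xx - cx
    xr = dx * np.cos(theta0) + dy * np.sin(theta0)
    yr = -dx * np.sin(theta0) + dy * np.cos(theta0)
    rho = np.hypot(xr / a, yr / b)
    ang = np.arctan2(yr / b, xr / a)
    boundary = 1.0 + spec.serration_amp * np.sin(spec.serration_freq * ang + phase)
    mask = rho <= boundary
    if not mask.any():
        raise InvalidParameterError("leaf mask is empty")

    img = np.full((size, size), spec.background)
    img += 0.01 * rng.standard_normal((size, size))

    interior_spec = spec.interior or TextureSpec(class_id=spec.class_id, bands=((0.15, 0.03, 1.0),))
    tex_i = bandpass_noise(interior_spec, size, _rng_for(seed, 2000 + spec.class_id, index))
    obj = spec.object_level + spec.contrast * np.clip(tex_i, -2.5, 2.5) / 2.5
    if spec.border is not None:
        tex_b = bandpass_noise(spec.border, size, _rng_for(seed, 3000 + spec.class_id, index))
        dist = ndimage.distance_transform_edt(mask)
        band = mask & (dist <= spec.border_width)
        obj = np.where(band, spec.object_level + spec.contrast * np.clip(tex_b, -2.5, 2.5) / 2.5, obj)
    img[mask] = obj[mask]
    return np.clip(img, 0.0, 1.0), mask


def gen_leaf_dataset(
    specs: list[LeafSpec],
    n_per_class: int,
    seed: int = 0,
    size: int = 128,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Leaf images, ground-truth masks, and labels for a list of class specs."""
    if len(specs) < 2:
        raise InvalidParameterError("need at least 2 leaf specs")
    images, masks, labels = [], [], []
    for spec in specs:
        for i in range(n_per_class):
            img, mask = leaf_instance(spec, size, seed, i)
            images.append(img)
            masks.append(mask)
            labels.append(spec.class_id)
    return images, masks, np.asarray(labels)


def border_contrast_leaf_specs(n_classes: int = 3) -> list[LeafSpec]:
    """Leaf classes identical in the interior, differing only in border
    texture and serration: a fixture for border-information experiments."""
    shared_interior = TextureSpec(class_id=0, bands=((0.14, 0.025, 1.0),))
    border_freqs = np.linspace(0.10, 0.38, n_classes)
    specs = []
    for k in range(n_classes):
        specs.append(
            LeafSpec(
                class_id=k,
                interior=shared_interior,
                border=TextureSpec(class_id=k, bands=((float(border_freqs[k]), 0.02, 1.0),)),
                serration_freq=8 + 6 * k,
                serration_amp=0.03 + 0.015 * k,
                border_width=5.0,
            )
        )
    return specs
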