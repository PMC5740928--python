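"""Rotation-orbit algebra of P-bit circular binary codes.

A P-bit code assigns bit p (weight ``2**p``) to the sample at angle
``2*pi*p/P``, with sample 0 due east and angles increasing
counter-clockwise.  Cyclic bit rotation of a code corresponds to a
rigid rotation of the sampling circle, so the orbits of the rotation
action are exactly the sets of patterns that are indistinguishable up
to image rotation (binary necklaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

MAX_P = 24


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling geometry: P points on a circle of radius R."""

    P: int = 8
    R: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.P <= MAX_P):
            raise InvalidParameterError(f"P must be in [1, {MAX_P}], got {self.P}")
        if not self.R > 0:
            raise InvalidParameterError(f"R must be positive, got {self.R}")


def _check_code(code: int, P: int) -> None:
    if not (1 <= P <= MAX_P):
        raise InvalidParameterError(f"P must be in [1, {MAX_P}], got {P}")
    if not (0 <= code < (1 << P)):
        raise InvalidParameterError(f"code {code} out of range for P={P}")


def rotate_code(code: int, k: int, P: int) -> int:
    """Cyclically rotate ``code`` by ``k`` bit positions (bit p -> bit (p+k) mod P)."""
    _check_code(code, P)
    k %= P
    mask = (1 << P) - 1
    return ((code << k) | (code >> (P - k))) & mask if k else code


def _rotate_codes(codes: np.ndarray, k: int, P: int) -> np.ndarray:
    """Vectorized rotate_code on an integer array."""
    k %= P
    if k == 0:
        return codes.copy()
    mask = (1 << P) - 1
    return ((codes << k) | (codes >> (P - k))) & mask


def classify_uniformity(code: int, P: int) -> tuple[int, bool]:
    """Return (circular 0-1 transition count, is_uniform).

    A code is uniform when it has at most 2 circular transitions.
    """
    _check_code(code, P)
    transitions = int(bin(code ^ rotate_code(code, 1, P)).count("1"))
    return transitions, transitions <= 2


def code_period(code: int, P: int) -> int:
    """Smallest d > 0 with rotate_code(code, d, P) == code; d divides P."""
    _check_code(code, P)
    for d in range(1, P + 1):
        if P % d == 0 and rotate_code(code, d, P) == code:
            return d
    raise AssertionError("unreachable: rotation by P is the identity")


def necklace_count(P: int) -> int:
    """Number of binary necklaces of length P (Burnside closed form)."""
    from math import gcd

    def phi(n: int) -> int:
        return sum(1 for k in range(1, n + 1) if gcd(k, n) == 1)

    return sum(phi(d) * 2 ** (P // d) for d in range(1, P + 1) if P % d == 0) // P


@dataclass
class OrbitTable:
    """Partition of all 2**P codes into rotation orbits.

    Per-code arrays (length ``2**P``): ``orbit_id``, ``rotation_index``,
    ``period``, ``ones``, ``transitions``, ``uniform``.  Per-orbit:
    ``canonical`` (minimum member, ascending order), ``orbit_period``,
    and ``members`` (ordered by rotation index).
    """

    P: int
    orbit_id: np.ndarray
    rotation_index: np.ndarray
    period: np.ndarray
    ones: np.ndarray
    transitions: np.ndarray
    uniform: np.ndarray
    canonical: np.ndarray
    orbit_period: np.ndarray
    members: list[np.ndarray] = field(repr=False)

    @property
    def n_orbits(self) -> int:
        return len(self.canonical)

    @property
    def orbit_uniform(self) -> np.ndarray:
        """Per-orbit uniformity flag (uniformity is rotation-invariant)."""
        return self.uniform[self.canonical]

    def to_frame(self) -> pd.DataFrame:
        """Per-code table for export/debugging."""
        codes = np.arange(1 << self.P)
        return pd.DataFrame(
            {
                "code": codes,
                "orbit_id": self.orbit_id,
                "rotation_index": self.rotation_index,
                "period": self.period,
                "ones": self.ones,
                "transitions": self.transitions,
                "uniform": self.uniform,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_orbits(P: int) -> OrbitTable:
    """Enumerate the complete rotation-orbit partition of all 2**P codes."""
    if not (1 <= P <= MAX_P):
        raise InvalidParameterError(f"P must be in [1, {MAX_P}], got {P}")
    n = 1 << P
    codes = np.arange(n, dtype=np.int64)

    # canonical = minimum over all rotations
    canonical_of = codes.copy()
    for k in range(1, P):
        np.minimum(canonical_of, _rotate_codes(codes, k, P), out=canonical_of)

    # period = smallest divisor d of P fixing the code
    period = np.full(n, P, dtype=np.int64)
    for d in sorted((d for d in range(1, P) if P % d == 0), reverse=True):
        period[_rotate_codes(codes, d, P) == codes] = d

    # rotation index: smallest r with rotate(canonical, r) == code
    rotation_index = np.zeros(n, dtype=np.int64)
    assigned = canonical_of == codes
    for r in range(1, P):
        hit = (_rotate_codes(canonical_of, r, P) == codes) & ~assigned
        rotation_index[hit] = r
        assigned |= hit

    ones = np.bitwise_count(codes.astype(np.uint64)).astype(np.int64)
    transitions = np.bitwise_count(
        (codes ^ _rotate_codes(codes, 1, P)).astype(np.uint64)
    ).astype(np.int64)
    uniform = transitions <= 2

    canonical = np.unique(canonical_of)  # ascending canonical order
    orbit_id = np.searchsorted(canonical, canonical_of)
    orbit_period = period[canonical]
    members = []
    for oid, can in enumerate(canonical):
        d = orbit_period[oid]
        members.append(
            np.array([rotate_code(int(can), r, P) for r in range(d)], dtype=np.int64)
        )
    return OrbitTable(
        P=P,
        orbit_id=orbit_id,
        rotation_index=rotation_index,
        period=period,
        ones=ones,
        transitions=transitions,
        uniform=uniform,
        canonical=canonical,
        orbit_period=orbit_period,
        members=members,
    )
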