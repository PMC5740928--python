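"""Rotation-invariant histogram-Fourier features from LBP code images.

Per orbit of period d, the occurrence histogram (ordered by rotation
index) is transformed by a length-d DFT; the magnitudes of the first
``d//2 + 1`` coefficients are invariant to cyclic rotation of the
underlying patterns.  Additional invariants couple the u=1 coefficients
of adjacent orbits, whose phases cancel under a common rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .lbp import CodeImage
from .patterns import OrbitTable


@dataclass
class OrbitHistogram:
    """Per-orbit pattern frequencies ordered by rotation index.

    ``hists[oid]`` has length equal to the orbit period.  Raw counts
    are divided by the total valid-pixel count so that descriptors are
    comparable across region sizes; ``total`` keeps the raw count.
    """

    hists: list[np.ndarray]
    total: int

    @property
    def empty(self) -> bool:
        return self.total == 0


def orbit_histogram(codes: CodeImage, table: OrbitTable) -> OrbitHistogram:
    """Tally valid codes into per-orbit, per-rotation-index frequency bins."""
    if codes.P != table.P:
        raise InvalidParameterError("code image and orbit table disagree on P")
    counts = np.bincount(codes.codes[codes.valid].ravel(), minlength=1 << table.P)
    total = int(counts.sum())
    scale = 1.0 / total if total else 0.0
    hists = []
    for oid in range(table.n_orbits):
        members = table.members[oid]
        hists.append(counts[members].astype(np.float64) * scale)
    return OrbitHistogram(hists=hists, total=total)


@dataclass
class SpectralBlock:
    """Per-orbit complex DFT coefficients of the orbit histograms."""

    coeffs: list[np.ndarray]  # coeffs[oid] has length = orbit period


def orbit_spectra(hist: OrbitHistogram, table: OrbitTable) -> SpectralBlock:
    return SpectralBlock(coeffs=[np.fft.fft(h) for h in hist.hists])


def _orbit_selection(table: OrbitTable, mode: str) -> np.ndarray:
    if mode == "full":
        return np.arange(table.n_orbits)
    if mode == "uniform":
        # uniform orbits of period >= 2; the two constant orbits are
        # reported separately as extra bins
        sel = np.flatnonzero(table.orbit_uniform & (table.orbit_period >= 2))
        return sel
    raise InvalidParameterError(f"unknown mode {mode!r}")


def hf_magnitudes(
    hist: OrbitHistogram,
    table: OrbitTable,
    mode: str = "full",
    spectra: SpectralBlock | None = None,
) -> np.ndarray:
    """DFT magnitude features: |H(n, u)| for u = 0..d//2 per selected orbit.

    In uniform mode three extra bins follow the magnitudes: the two
    constant-pattern frequencies (all-zeros, all-ones) and the pooled
    frequency of all non-uniform patterns.
    """
    if spectra is None:
        spectra = orbit_spectra(hist, table)
    sel = _orbit_selection(table, mode)
    parts = []
    for oid in sel:
        d = table.orbit_period[oid]
        parts.append(np.abs(spectra.coeffs[oid][: d // 2 + 1]))
    if mode == "uniform":
        all_zeros = hist.hists[table.orbit_id[0]][0]
        all_ones_code = (1 << table.P) - 1
        all_ones = hist.hists[table.orbit_id[all_ones_code]][0]
        nonuni = sum(
            h.sum()
            for oid, h in enumerate(hist.hists)
            if not table.orbit_uniform[oid]
        )
        parts.append(np.array([all_zeros, all_ones, nonuni]))
    return np.concatenate(parts) if parts else np.zeros(0)


def _hf_plus_pairs(table: OrbitTable, mode: str) -> list[tuple[int, int]]:
    """Adjacent orbit pairs (canonical order) restricted to equal periods.

    Under a k-step pattern rotation the u=1 coefficient of a period-d
    orbit picks up the phase exp(-i*2*pi*k/d), so the coupled product
    H(n,1)*conj(H(n+1,1)) is rotation-invariant only when both orbits
    share the same period; orbits of period < 2 have no u=1 coefficient
    and are skipped entirely.
    """
    sel = [
        oid for oid in _orbit_selection(table, mode) if table.orbit_period[oid] >= 2
    ]
    by_period: dict[int, list[int]] = {}
    for oid in sel:  # sel is in canonical order
        by_period.setdefault(int(table.orbit_period[oid]), []).append(oid)
    pairs = []
    for d in sorted(by_period):
        group = by_period[d]
        pairs.extend(zip(group[:-1], group[1:]))
    return pairs


def hf_plus(
    spectra: SpectralBlock, table: OrbitTable, mode: str = "full"
) -> np.ndarray:
    """Coupled first-coefficient invariants for adjacent equal-period orbits.

    z = H(n,1) * conj(H(n+1,1)) is rotation-invariant; the principal
    complex square root w of z is emitted as (Re w, Im w).
    """
    out = []
    for a, b in _hf_plus_pairs(table, mode):
        z = spectra.coeffs[a][1] * np.conj(spectra.coeffs[b][1])
        w = np.sqrt(z + 0j)
        out.extend([w.real, w.imag])
    return np.asarray(out)


def n_hf_plus_pairs(table: OrbitTable, mode: str) -> int:
    return len(_hf_plus_pairs(table, mode))


def hf_block_length(table: OrbitTable, mode: str) -> int:
    """Number of |H| magnitude entries per LBP type (incl. uniform extras)."""
    sel = _orbit_selection(table, mode)
    n = int(sum(table.orbit_period[oid] // 2 + 1 for oid in sel))
    if mode == "uniform":
        n += 3
    return n


def scale_descriptor_length(table: OrbitTable, mode: str, plus: bool) -> int:
    n = 2 * hf_block_length(table, mode)
    if plus:
        n += 2 * 2 * n_hf_plus_pairs(table, mode)
    return n


def descriptor_layout(table: OrbitTable, mode: str, plus: bool) -> dict[str, list[int]]:
    """Entry-name -> [start, stop) index ranges of one per-scale descriptor."""
    hf_len = hf_block_length(table, mode)
    plus_len = 2 * n_hf_plus_pairs(table, mode) if plus else 0
    layout = {}
    pos = 0
    for name, ln in (
        ("hf_sign", hf_len),
        ("hf_magnitude", hf_len),
        ("hf_plus_sign", plus_len),
        ("hf_plus_magnitude", plus_len),
    ):
        if ln:
            layout[name] = [pos, pos + ln]
            pos += ln
    return layout


def signed_entry_mask(table: OrbitTable, mode: str, plus: bool) -> np.ndarray:
    """Boolean mask over one per-scale descriptor: True where entries may be negative."""
    n = scale_descriptor_length(table, mode, plus)
    mask = np.zeros(n, dtype=bool)
    layout = descriptor_layout(table, mode, plus)
    for name in ("hf_plus_sign", "hf_plus_magnitude"):
        if name in layout:
            a, b = layout[name]
            mask[a:b] = True
    return mask


@dataclass
class ScaleDescriptor:
    """Concatenated HF features of one scale: [HF-S | HF-M | HF+S | HF+M]."""

    values: np.ndarray
    scale_index: int
    empty: bool


def scale_descriptor(
    sign_codes: CodeImage,
    mag_codes: CodeImage,
    table: OrbitTable,
    mode: str = "full",
    plus: bool = True,
    scale_index: int = 0,
) -> ScaleDescriptor:
    if sign_codes.P != mag_codes.P or sign_codes.P != table.P:
        raise InvalidParameterError("P mismatch between code images and orbit table")
    n = scale_descriptor_length(table, mode, plus)
    if sign_codes.empty:
        return ScaleDescriptor(values=np.zeros(n), scale_index=scale_index, empty=True)
    mags, pluses = [], []
    for codes in (sign_codes, mag_codes):
        hist = orbit_histogram(codes, table)
        spectra = orbit_spectra(hist, table)
        mags.append(hf_magnitudes(hist, table, mode, spectra=spectra))
        if plus:
            pluses.append(hf_plus(spectra, table, mode))
    values = np.concatenate(mags + pluses)
    assert values.size == n
    return ScaleDescriptor(values=values, scale_index=scale_index, empty=False)
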