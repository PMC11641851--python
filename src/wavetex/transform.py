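"""Separable 2D multilevel discrete wavelet transform with symmetric extension.

The forward transform filters rows then columns with the decomposition pair,
downsampling dyadically, which yields four subbands per level: the
approximation ``cA`` (low/low) and the horizontal/vertical/diagonal details
``cH``/``cV``/``cD``.  Level ``k+1`` decomposes level ``k``'s approximation.

Boundary handling is half-point symmetric extension and the downsampling
phase follows the convention of the de-facto reference implementation
(PyWavelets, ``mode="symmetric"``); agreement is enforced elementwise in the
test suite.  Subband dimensions are ``floor((n + taps - 1) / 2)``.

The inverse transform exists for round-trip verification only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import FilterBank, filter_bank

__all__ = [
    "SubbandSet",
    "DecompositionPyramid",
    "dwt2_single_level",
    "wavedec2",
    "waverec2",
    "max_level",
]


@dataclass(frozen=True)
class SubbandSet:
    """One decomposition level: approximation plus three detail subbands."""

    level: int
    cA: np.ndarray
    cH: np.ndarray
    cV: np.ndarray
    cD: np.ndarray
    #: shape of the matrix this level was computed from (needed for inversion)
    input_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        shapes = {self.cA.shape, self.cH.shape, self.cV.shape, self.cD.shape}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")


@dataclass(frozen=True)
class DecompositionPyramid:
    """Ordered subband sets for levels 1..L of one image and one wavelet."""

    wavelet: str
    levels: tuple[SubbandSet, ...]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _analyze_1d(ext: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Full convolution along ``axis`` followed by dyadic downsampling.

    ``ext`` must already be symmetrically extended by ``taps - 1`` samples on
    both ends of ``axis``; the kept phase starts at index ``taps``.
    """
    taps = len(filt)
    out = np.apply_along_axis(lambda v: np.convolve(v, filt), axis, ext)
    sl = [slice(None)] * out.ndim
    n_in = ext.shape[axis] - 2 * (taps - 1)
    n_out = (n_in + taps - 1) // 2
    sl[axis] = slice(taps, taps + 2 * n_out, 2)
    return out[tuple(sl)]


def _dwt_axis(a: np.ndarray, fb: FilterBank, axis: int) -> tuple[np.ndarray, np.ndarray]:
    pad = [(0, 0)] * a.ndim
    pad[axis] = (fb.taps - 1, fb.taps - 1)
    ext = np.pad(a, pad, mode="symmetric")
    return _analyze_1d(ext, fb.dec_lo, axis), _analyze_1d(ext, fb.dec_hi, axis)


def dwt2_single_level(image: np.ndarray, fb: FilterBank, level: int = 1) -> SubbandSet:
    """One analysis level of the separable 2D DWT.

    Parameters
    ----------
    image
        Finite real matrix, both dimensions at least 2.
    fb
        Filter bank from :func:`wavetex.filters.filter_bank`.
    level
        Label stored on the returned :class:`SubbandSet` (pyramid position).
    """
    a = np.asarray(image, dtype=float)
    if a.ndim != 2 or min(a.shape) < 2:
        raise ValueError(f"need a 2D matrix with both dims >= 2, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    lo, hi = _dwt_axis(a, fb, axis=1)  # rows
    cA, cH = _dwt_axis(lo, fb, axis=0)  # columns of the low-pass half
    cV, cD = _dwt_axis(hi, fb, axis=0)
    return SubbandSet(level=level, cA=cA, cH=cH, cV=cV, cD=cD, input_shape=a.shape)


_LEVEL_CAP = 32  # depth at which any practical image is exhausted


def max_level(shape: tuple[int, int], fb: FilterBank) -> int:
    """Largest decomposition depth whose every stage sees a matrix >= 2x2.

    Under symmetric extension the size recurrence n -> floor((n+taps-1)/2)
    can reach a fixed point above 2 for wide filters, in which case depth is
    effectively unbounded and the cap is returned.
    """
    n = min(shape)
    lvl = 0
    while n >= 2 and lvl < _LEVEL_CAP:
        lvl += 1
        nxt = (n + fb.taps - 1) // 2
        if nxt >= n:
            return _LEVEL_CAP
        n = nxt
    return lvl


def wavedec2(image: np.ndarray, fb: FilterBank | str, L: int) -> DecompositionPyramid:
    """Multilevel 2D decomposition: L successive single-level transforms.

    Raises
    ------
    ValueError
        If ``L`` exceeds the maximum feasible depth for the image size.
    """
    if isinstance(fb, str):
        fb = filter_bank(fb)
    if L < 1:
        raise ValueError("L must be >= 1")
    a = np.asarray(image, dtype=float)
    feasible = max_level(a.shape, fb)
    if L > feasible:
        raise ValueError(
            f"level {L} infeasible for shape {a.shape} with {fb.name} "
            f"({fb.taps} taps); maximum feasible level is {feasible}"
        )
    levels = []
    cur = a
    for k in range(1, L + 1):
        sb = dwt2_single_level(cur, fb, level=k)
        levels.append(sb)
        cur = sb.cA
    return DecompositionPyramid(wavelet=fb.name, levels=tuple(levels))


def _idwt_axis(lo: np.ndarray, hi: np.ndarray, fb: FilterBank, axis: int,
               out_len: int) -> np.ndarray:
    taps = fb.taps
    L = lo.shape[axis]

    def up(v: np.ndarray, filt: np.ndarray) -> np.ndarray:
        u = np.zeros(2 * len(v))
        u[::2] = v
        return np.convolve(u, filt)

    ylo = np.apply_along_axis(lambda v: up(v, fb.rec_lo), axis, lo)
    yhi = np.apply_along_axis(lambda v: up(v, fb.rec_hi), axis, hi)
    y = ylo + yhi
    full = 2 * L - taps + 2
    sl = [slice(None)] * y.ndim
    sl[axis] = slice(taps - 2, taps - 2 + full)
    y = y[tuple(sl)]
    # a transform of an odd-length axis produces one synthesis sample extra
    sl[axis] = slice(0, out_len)
    return y[tuple(sl)]


def _idwt2(sb: SubbandSet, fb: FilterBank) -> np.ndarray:
    rows, cols = sb.input_shape
    lo = _idwt_axis(sb.cA, sb.cH, fb, axis=0, out_len=rows)
    hi = _idwt_axis(sb.cV, sb.cD, fb, axis=0, out_len=rows)
    return _idwt_axis(lo, hi, fb, axis=1, out_len=cols)


def waverec2(pyramid: DecompositionPyramid, fb: FilterBank | str) -> np.ndarray:
    """Invert :func:`wavedec2`; reconstructs the input to ~1e-10."""
    if isinstance(fb, str):
        fb = filter_bank(fb)
    if fb.name != pyramid.wavelet:
        raise ValueError(
            f"filter bank {fb.name!r} does not match pyramid wavelet {pyramid.wavelet!r}"
        )
    cur = pyramid.levels[-1].cA
    for sb in reversed(pyramid.levels):
        sb = SubbandSet(sb.level, cur, sb.cH, sb.cV, sb.cD, sb.input_shape)
        cur = _idwt2(sb, fb)
    return cur
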