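"""The Haar-Fisz variance-stabilizing transform.

For a nonnegative vector with multiplicative chi-square-like noise the
transform takes the Haar pyramid, divides each detail coefficient by its
companion scaling coefficient (the Fisz ratio f = d/c), and rebuilds a
vector from the ratios.  The result is approximately Gaussian with
near-constant variance, and the operation is exactly invertible on
positive inputs.  Applied row-by-row to the raw wavelet periodogram it
turns spectrum estimation into a standard signal-plus-Gaussian-noise
wavelet regression at each scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelets import _check_dyadic

__all__ = [
    "HFField",
    "haar_fisz_forward",
    "haar_fisz_inverse",
    "haar_fisz_rows",
    "haar_fisz_inverse_rows",
]

_SQRT2 = np.sqrt(2.0)


def haar_fisz_forward(
    v: np.ndarray, return_flags: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Forward Haar-Fisz transform of a nonnegative vector of length 2^J.

    Wherever a scaling coefficient c_{l,m} is zero the Fisz ratio is set
    to zero (the input is identically zero on that dyadic block, and
    reconstructs as such).  With ``return_flags=True`` a boolean vector
    marks the time positions covered by any zero scaling coefficient.
    """
    v = np.asarray(v, dtype=float)
    J = _check_dyadic(v.size)
    if np.any(v < 0):
        raise ValueError("Haar-Fisz input must be nonnegative")
    flags = np.zeros(v.size, dtype=bool)
    c = v.copy()
    ratios = []  # finest first
    for level in range(J):
        even, odd = c[0::2], c[1::2]
        d = (even - odd) / _SQRT2
        c = (even + odd) / _SQRT2
        zero = c == 0.0
        if np.any(zero):
            block = v.size // c.size
            flags |= np.repeat(zero, block)
        f = np.divide(d, c, out=np.zeros_like(d), where=~zero)
        ratios.append(f)
    h = c  # single overall scaling coefficient, kept as-is
    for f in reversed(ratios):
        nxt = np.empty(2 * h.size)
        nxt[0::2] = h + f
        nxt[1::2] = h - f
        h = nxt
    return (h, flags) if return_flags else h


def haar_fisz_inverse(h: np.ndarray) -> np.ndarray:
    """Inverse Haar-Fisz transform.

    Recovers the Fisz ratios by a plain Haar-style pyramid on ``h`` and
    rebuilds the original pyramid with d = f * c.  Exact inverse of
    :func:`haar_fisz_forward` on strictly positive inputs; dyadic blocks
    that were identically zero reconstruct as zeros.
    """
    h = np.asarray(h, dtype=float)
    _check_dyadic(h.size)
    c = h.copy()
    ratios = []
    while c.size > 1:
        even, odd = c[0::2], c[1::2]
        ratios.append((even - odd) / 2.0)
        c = (even + odd) / 2.0
    v = c
    for f in reversed(ratios):
        d = f * v
        nxt = np.empty(2 * v.size)
        nxt[0::2] = (v + d) / _SQRT2
        nxt[1::2] = (v - d) / _SQRT2
        v = nxt
    return v


@dataclass
class HFField:
    """Haar-Fisz transformed periodogram: rows H_{j, .} = F I_{j, .}."""

    H: np.ndarray
    zero_flags: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape


def haar_fisz_rows(M: np.ndarray) -> HFField:
    """Apply the forward transform to every row of a nonnegative matrix."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    H = np.empty_like(M)
    flags = np.zeros(M.shape, dtype=bool)
    for i, row in enumerate(M):
        H[i], flags[i] = haar_fisz_forward(row, return_flags=True)
    return HFField(H, flags)


def haar_fisz_inverse_rows(H: np.ndarray) -> np.ndarray:
    """Apply the inverse transform to every row."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    return np.stack([haar_fisz_inverse(row) for row in H])
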