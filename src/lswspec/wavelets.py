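"""Discrete wavelet machinery.

Daubechies filters, the orthogonal (decimated) DWT and its inverse, the
non-decimated detail transform used to form the wavelet periodogram, and
discrete wavelet vectors obtained by the cascade recursion.

Scale conventions used throughout the package:

* *process* scales are ``j = 1, 2, ...`` with ``j = 1`` the finest;
* *DWT shrinkage* scales are ``l = 0, ..., J-1`` with ``l = 0`` the
  coarsest, holding a single detail coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt

__all__ = [
    "WaveletFilter",
    "build_filter",
    "dwt",
    "idwt",
    "ndwt_details",
    "discrete_wavelet",
]

#: families accepted by :func:`build_filter` and the vanishing-moment
#: ranges supported for each.
SUPPORTED = {
    "extremal-phase": range(1, 11),
    "least-asymmetric": range(4, 11),
    "haar": range(1, 2),
}

_ALIASES = {
    "ep": "extremal-phase",
    "extremal-phase": "extremal-phase",
    "extremal_phase": "extremal-phase",
    "la": "least-asymmetric",
    "least-asymmetric": "least-asymmetric",
    "least_asymmetric": "least-asymmetric",
    "haar": "haar",
}


@dataclass(frozen=True)
class WaveletFilter:
    """An orthonormal Daubechies wavelet filter.

    ``lowpass`` holds the synthesis (reconstruction) scaling filter; the
    quadrature-mirror highpass is derived from it.  Taps sum to sqrt(2)
    and have unit energy.
    """

    family: str
    vanishing_moments: int
    lowpass: tuple[float, ...] = field(repr=False)

    @property
    def name(self) -> str:
        short = {"extremal-phase": "ep", "least-asymmetric": "la", "haar": "haar"}
        if self.family == "haar":
            return "haar"
        return f"{short[self.family]}{self.vanishing_moments}"

    @property
    def pywt_name(self) -> str:
        if self.family == "least-asymmetric":
            return f"sym{self.vanishing_moments}"
        return f"db{self.vanishing_moments}"

    @property
    def highpass(self) -> tuple[float, ...]:
        h = self.lowpass
        L = len(h)
        return tuple((-1.0) ** n * h[L - 1 - n] for n in range(L))

    def __len__(self) -> int:
        return len(self.lowpass)


def build_filter(family: str, vm: int = 1) -> WaveletFilter:
    """Build a Daubechies wavelet filter.

    Parameters
    ----------
    family:
        ``"extremal-phase"`` (alias ``"ep"``), ``"least-asymmetric"``
        (alias ``"la"``) or ``"haar"``.  A compact name such as
        ``"la6"`` or ``"ep10"`` is also accepted.
    vm:
        Number of vanishing moments: 1-10 for extremal phase, 4-10 for
        least asymmetric.  ``ep`` with one vanishing moment *is* the
        Haar filter.

    Raises
    ------
    ValueError
        For an unsupported family / vanishing-moment pair.
    """
    key = str(family).strip().lower()
    # accept compact "ep3" / "la6" spellings
    if key not in _ALIASES:
        head = key.rstrip("0123456789")
        tail = key[len(head):]
        if head in _ALIASES and tail:
            key, vm = head, int(tail)
    if key not in _ALIASES:
        raise ValueError(f"unknown wavelet family: {family!r}")
    fam = _ALIASES[key]
    if vm not in SUPPORTED[fam]:
        raise ValueError(
            f"{fam} with {vm} vanishing moments is not supported "
            f"(allowed: {list(SUPPORTED[fam])})"
        )
    if fam == "haar":
        w = pywt.Wavelet("db1")
    else:
        w = pywt.Wavelet(f"sym{vm}" if fam == "least-asymmetric" else f"db{vm}")
    return WaveletFilter(fam, vm, tuple(w.rec_lo))


def _check_dyadic(n: int) -> int:
    J = int(round(np.log2(n))) if n > 0 else -1
    if J < 0 or 2**J != n:
        raise ValueError(f"length {n} is not a positive power of two")
    return J


def dwt(x: np.ndarray, f: WaveletFilter) -> list[np.ndarray]:
    """Full-depth orthogonal DWT with periodic boundaries.

    Returns ``[scaling, d_0, d_1, ..., d_{J-1}]`` where ``scaling`` is the
    single father-wavelet coefficient, ``d_l`` the detail coefficients at
    shrinkage scale ``l`` (``l = 0`` coarsest, one coefficient;
    ``l = J-1`` finest, ``2^{J-1}`` coefficients).
    """
    x = np.asarray(x, dtype=float)
    J = _check_dyadic(x.size)
    with warnings.catch_warnings():
        # full-depth periodized transforms are intentional here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, f.pywt_name, mode="periodization", level=J)
    return [np.asarray(c, dtype=float) for c in coeffs]


def idwt(coeffs: list[np.ndarray], f: WaveletFilter) -> np.ndarray:
    """Inverse of :func:`dwt` (exact round-trip)."""
    J = len(coeffs) - 1
    for l, c in enumerate(coeffs[1:]):
        if len(c) != 2**l:
            raise ValueError(
                f"detail scale {l} has {len(c)} coefficients, expected {2 ** l}"
            )
    if len(coeffs[0]) != 1:
        raise ValueError("expected a single scaling coefficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return np.asarray(
            pywt.waverec(list(coeffs), f.pywt_name, mode="periodization"), dtype=float
        )


@lru_cache(maxsize=256)
def _psi_cached(family: str, vm: int, j: int) -> np.ndarray:
    f = build_filter(family, vm)
    g = np.asarray(f.highpass, dtype=float)
    h = np.asarray(f.lowpass, dtype=float)
    psi = g
    for _ in range(1, j):
        up = np.zeros(2 * psi.size - 1)
        up[::2] = psi
        psi = np.convolve(up, h)
    return psi


def discrete_wavelet(j: int, f: WaveletFilter) -> np.ndarray:
    """Discrete wavelet vector at process scale ``j`` (``j = 1`` finest).

    Built by the cascade (upsample-and-convolve with the lowpass filter);
    unit Euclidean norm; support length ``(2^j - 1)(L_1 - 1) + 1``.
    """
    if j < 1:
        raise ValueError("scale j must be >= 1")
    return _psi_cached(f.family, f.vanishing_moments, int(j)).copy()


def _psi_wrapped(j: int, f: WaveletFilter, T: int) -> np.ndarray:
    """psi_j folded onto Z_T (for circular convolution of length T)."""
    psi = _psi_cached(f.family, f.vanishing_moments, int(j))
    out = np.zeros(T)
    np.add.at(out, np.arange(psi.size) % T, psi)
    return out


def ndwt_details(
    x: np.ndarray,
    f: WaveletFilter,
    J_max: int | None = None,
    boundary: str = "periodic",
) -> np.ndarray:
    """Non-decimated detail coefficients at every shift.

    Row ``j-1`` (for ``j = 1..J_max``) holds
    ``d_{j,k} = sum_t x_t psi_j(k - t)`` for ``k = 0..T-1``.  With the
    default periodic boundary the series is wrapped circularly; with
    ``boundary="zero"`` it is zero-extended outside ``0..T-1``.
    """
    x = np.asarray(x, dtype=float)
    T = x.size
    J = _check_dyadic(T)
    if J_max is None:
        J_max = J
    if not 1 <= J_max <= J:
        raise ValueError(f"J_max must be in 1..{J}, got {J_max}")
    if boundary not in ("periodic", "zero"):
        raise ValueError(f"unknown boundary rule: {boundary!r}")
    out = np.empty((J_max, T))
    if boundary == "periodic":
        fx = np.fft.rfft(x)
        for j in range(1, J_max + 1):
            fp = np.fft.rfft(_psi_wrapped(j, f, T))
            out[j - 1] = np.fft.irfft(fx * fp, n=T)
    else:
        for j in range(1, J_max + 1):
            psi = discrete_wavelet(j, f)
            out[j - 1] = np.convolve(x, psi)[:T]
    return out
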