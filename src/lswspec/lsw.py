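"""The locally stationary wavelet (LSW) process model.

An LSW process is a zero-mean Gaussian time series built from random
amplitudes attached to non-decimated wavelets,

    X_t = sum_j sum_k w_{j,k} psi_j(k - t) xi_{j,k},    xi_{j,k} ~ N(0, 1),

whose second-order structure is carried by the evolutionary wavelet
spectrum (EWS) S_j(z) = w_{j, zT}^2 in rescaled time z = k/T.  This
module provides the EWS container, autocorrelation wavelets, the
inner-product matrix A that biases the raw periodogram, and a simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .wavelets import WaveletFilter, discrete_wavelet, _check_dyadic, _psi_wrapped

__all__ = ["EWS", "acw", "inner_product_matrix", "simulate_lsw"]


@dataclass
class EWS:
    """Evolutionary wavelet spectrum on a dyadic grid.

    ``S`` is a ``J x T`` matrix with ``S[j-1, k] = S_j(k/T)``; row 0 is
    the finest scale ``j = 1``.  Entries are nonnegative; ``J = log2 T``.
    """

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        J, T = self.S.shape
        if _check_dyadic(T) != J:
            raise ValueError(f"EWS must be log2(T) x T, got {J} x {T}")
        if np.any(self.S < 0):
            raise ValueError("spectrum entries must be nonnegative")

    @property
    def n_scales(self) -> int:
        return self.S.shape[0]

    @property
    def n_times(self) -> int:
        return self.S.shape[1]


@lru_cache(maxsize=256)
def _acw_cached(family: str, vm: int, j: int) -> np.ndarray:
    from .wavelets import build_filter

    psi = discrete_wavelet(j, build_filter(family, vm))
    return np.correlate(psi, psi, mode="full")


def acw(j: int, f: WaveletFilter) -> np.ndarray:
    """Discrete autocorrelation wavelet Psi_j(tau) = sum_k psi_j(k) psi_j(k-tau).

    Returns the values on ``tau = -(L_j-1), ..., 0, ..., L_j-1`` (length
    ``2 L_j - 1``, centre index ``L_j - 1``).  Symmetric in tau with
    ``Psi_j(0) = 1``.
    """
    if j < 1:
        raise ValueError("scale j must be >= 1")
    return _acw_cached(f.family, f.vanishing_moments, int(j)).copy()


def inner_product_matrix(J: int, f: WaveletFilter) -> np.ndarray:
    """Gram matrix A of the autocorrelation wavelets.

    ``A[j-1, l-1] = <Psi_j, Psi_l> = sum_tau Psi_j(tau) Psi_l(tau)`` for
    process scales ``1..J``.  Symmetric positive definite; it maps the
    true spectrum to the expected raw periodogram (column-wise), and its
    inverse de-biases the periodogram.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    tables = [acw(j, f) for j in range(1, J + 1)]
    A = np.empty((J, J))
    for a in range(J):
        for b in range(a, J):
            ta, tb = tables[a], tables[b]
            ca, cb = (ta.size - 1) // 2, (tb.size - 1) // 2
            m = min(ca, cb)
            A[a, b] = A[b, a] = float(
                np.dot(ta[ca - m : ca + m + 1], tb[cb - m : cb + m + 1])
            )
    return A


def simulate_lsw(
    spec: EWS,
    f: WaveletFilter,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one realization of the LSW process with spectrum ``spec``.

    Amplitudes are ``w_{j,k} = sqrt(S_j(k/T))`` with iid standard normal
    innovations; synthesis uses the non-decimated wavelets of ``f`` with
    circular wrap-around.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    S = spec.S
    J, T = S.shape
    x = np.zeros(T)
    amp = np.sqrt(S)
    for j in range(1, J + 1):
        if not np.any(amp[j - 1]):
            continue
        a = amp[j - 1] * rng.standard_normal(T)
        fp = np.fft.rfft(_psi_wrapped(j, f, T))
        # X_t = sum_k a_k psi_j(k - t): circular cross-correlation
        x += np.fft.irfft(np.fft.rfft(a) * np.conj(fp), n=T)
    return x
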