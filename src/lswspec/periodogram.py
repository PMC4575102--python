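"""Raw wavelet periodogram and its inner-product-matrix bias correction.

The raw periodogram I_{j,k} = |d_{j,k}|^2 (squared non-decimated detail
coefficients) has expectation (A S)_j(k/T) + O(1/T): it is biased by the
Gram matrix A of the autocorrelation wavelets and is not consistent.
``correct_bias`` applies A^{-1} column-wise; smoothing happens elsewhere.
"""

from __future__ import annotations

import numpy as np

from .wavelets import WaveletFilter, ndwt_details

__all__ = ["raw_wavelet_periodogram", "correct_bias"]


def raw_wavelet_periodogram(
    x: np.ndarray,
    f: WaveletFilter,
    J_max: int | None = None,
    boundary: str = "periodic",
) -> np.ndarray:
    """Squared non-decimated detail coefficients, rows j = 1 (finest) down."""
    d = ndwt_details(x, f, J_max=J_max, boundary=boundary)
    return d**2


def correct_bias(M: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Apply A^{-1} to every time-column of a J x T matrix.

    Linear; negative output entries are legitimate (the correction is
    applied before any clipping so that credible-interval propagation
    stays linear).
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[0] != M.shape[0]:
        raise ValueError(
            f"A must be square with side {M.shape[0]}, got {A.shape}"
        )
    return np.linalg.solve(A, M)
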