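"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed forms in ``lswspec.shrinkage``:
every quantity is computed by adaptive quadrature of its defining
integral (slab moments, slab marginal, posterior moments, mixture
log-likelihood).
"""

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def q_moment_quad(h: float, nu: float, tau: float, i: int) -> float:
    """int x^i (tau/2) e^{-tau|x|} phi_nu(x - h) dx by adaptive quadrature.

    Integrates over the Gaussian mass split at the Laplace kink to keep
    the quadrature reliable in the tails.
    """

    def f(x):
        return x**i * 0.5 * tau * np.exp(-tau * abs(x)) * norm.pdf(x - h, scale=nu)

    lo, hi = h - 12 * nu, h + 12 * nu
    pts = sorted({lo, min(max(0.0, lo), hi), hi})
    return sum(
        quad(f, a, b, limit=200, epsabs=1e-300, epsrel=1e-12)[0]
        for a, b in zip(pts[:-1], pts[1:])
    )


def posterior_moments_quad(h: float, alpha: float, tau: float, nu: float):
    """Posterior mean / variance / spike mass by quadrature of the mixture."""
    theta = alpha / (1.0 - alpha)
    q0 = q_moment_quad(h, nu, tau, 0)
    q1 = q_moment_quad(h, nu, tau, 1)
    q2 = q_moment_quad(h, nu, tau, 2)
    denom = theta * norm.pdf(h, scale=nu) + q0
    mean = q1 / denom
    var = q2 / denom - mean**2
    w0 = theta * norm.pdf(h, scale=nu) / denom
    return mean, var, w0


def loglik_quad(alpha: float, tau: float, nu: float, h) -> float:
    """Mixture marginal log-likelihood via the quadrature slab marginal."""
    tot = 0.0
    for y in np.asarray(h, dtype=float).ravel():
        g = q_moment_quad(y, nu, tau, 0)
        tot += np.log(alpha * norm.pdf(y, scale=nu) + (1.0 - alpha) * g)
    return tot
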