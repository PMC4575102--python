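# lswspec

Evolutionary wavelet spectrum estimation for locally stationary time
series, with credible intervals.

Many biomedical and environmental time series — infant heart rate,
EEG, wind speed — are nonstationary: their second-order structure
(variance, autocovariance) drifts over time.  The locally stationary
wavelet (LSW) model represents such a series of dyadic length
`T = 2^J` as a sum of randomly amplified non-decimated wavelets,

    X_t = Σ_j Σ_k w_{j,k} ψ_{j,k−t} ξ_{j,k},      ξ_{j,k} ~ N(0,1),

and summarizes its time-varying second-order structure by the
evolutionary wavelet spectrum (EWS) `S_j(z) = w²_{j,⌊zT⌋}`, the variance
contribution at scale `j` (j = 1 finest) and rescaled time `z = k/T`.

The raw wavelet periodogram `I_{j,k}` (squared non-decimated wavelet
coefficients) estimates `(A S)_j(z)` only in expectation — biased by
the autocorrelation-wavelet Gram matrix `A` — and is inconsistent, so
it must be smoothed.  `lswspec` smooths it with an empirical-Bayes
method: each scale row is variance-stabilized by the invertible
Haar-Fisz transform `F` (Fisz ratios `d/c` of the Haar pyramid), the
stabilized row's wavelet coefficients get a spike-and-slab prior
`α δ₀ + (1−α) Laplace(τ)` with per-scale hyperparameters `(α, τ, ν)`
fitted by marginal maximum likelihood, and the posterior-mean field is
mapped back through `F⁻¹` and `A⁻¹` with cycle spinning.  Posterior
draws pushed through the same maps yield pointwise credible bands for
the spectrum — the main practical benefit over classical
translation-invariant (TI) soft-threshold smoothing, which the package
also implements as a baseline.

Audience: statisticians and analysts of nonstationary series who want
a spectrum estimate *with uncertainty*, plus a reproducible simulation
harness comparing the Bayesian estimator against TI denoising.

## Worked example

Simulate a process whose finest scale carries a burst of power and
estimate its spectrum:

```python
import numpy as np
from lswspec import (EWS, PipelineConfig, build_filter, simulate_lsw,
                     estimate_ews, canonical_spectrum, amse)

spec = canonical_spectrum(1024)        # sin^2 power at j=6, burst at j=1
x = simulate_lsw(spec, build_filter("haar"), seed=11)

cfg = PipelineConfig(smoothing_filter=build_filter("la", 6),
                     spins=20, n_samples=1000, seed=5)
est = estimate_ews(x, cfg)

print("AMSE vs truth:", round(amse(est.point, spec), 4))
lo, hi = est.bands[0.9]
z = np.arange(1024) / 1024
burst = (z >= 0.58) & (z < 0.66)
print("mean width of 90% band, finest scale:", round((hi[0] - lo[0]).mean(), 4))
print("mean estimate over the burst:", round(est.point[0][burst].mean(), 3),
      "| elsewhere:", round(est.point[0][~burst].mean(), 3))
```

prints

```
AMSE vs truth: 0.1295
mean width of 90% band, finest scale: 0.238
mean estimate over the burst: 1.082 | elsewhere: 0.044
```

The estimator recovers the burst (power ≈ 1.08 inside the interval
where the truth is 1, ≈ 0.04 elsewhere), and the 90% band quantifies
the pointwise uncertainty — widest exactly where the power estimate is
large, since the periodogram noise variance scales with the squared
signal.  `est.bands` holds lower/upper matrices per level; with
`clip_negative=True` the presentation is restricted to the physically
meaningful nonnegative range.

The same flow is available from the shell:

```sh
lswspec estimate x.csv --smooth-filter la6 --spins 20 --samples 1000 \
        --levels 0.5,0.9 --seed 5 --out est/
```

writing `point.csv`, `lower_50.csv` … `upper_90.csv`, `meta.json` and a
long-format `long.csv` to `est/`.  `lswspec simulate` draws LSW
realizations from a spectrum CSV, and `lswspec study` runs the method
comparison.  A one-column CSV of an ECG-like series can be differenced
on the way in with `--diff`.

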