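"""Error analysis for correlated Monte Carlo series.

Blocking (recursive pairwise averaging) gives asymptotically unbiased
standard errors for autocorrelated samples; the integrated
autocorrelation time estimator is used to pick history windows.
"""

from __future__ import annotations

import numpy as np

__all__ = ["reblocking_curve", "blocking_error", "integrated_autocorr_time"]


def reblocking_curve(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-error estimate at each blocking level.

    Returns (errors, block counts); level k averages 2^k consecutive
    samples.  Requires at least 16 samples.
    """
    x = np.asarray(samples, float)
    if x.ndim != 1:
        raise ValueError("reblocking expects a 1D series")
    if x.size < 16:
        raise ValueError("need at least 16 samples for blocking")
    errs, counts = [], []
    while x.size >= 2:
        n = x.size
        errs.append(np.sqrt(x.var(ddof=1) / n) if n > 1 else 0.0)
        counts.append(n)
        x = 0.5 * (x[: 2 * (n // 2) : 2] + x[1 : 2 * (n // 2) : 2])
    return np.array(errs), np.array(counts)


def blocking_error(samples: np.ndarray, min_blocks: int = 32) -> float:
    """Quoted statistical error: the plateau of the reblocking curve.

    The plateau is taken as the largest error estimate among levels that
    still have at least ``min_blocks`` blocks, which is where the curve
    flattens for correlated data while remaining statistically stable.
    """
    errs, counts = reblocking_curve(samples)
    usable = errs[counts >= min_blocks]
    if usable.size == 0:
        usable = errs[:1]
    return float(usable.max())


def integrated_autocorr_time(samples: np.ndarray, c: float = 5.0) -> float:
    """Sokal-windowed integrated autocorrelation time (in steps, >= 1).

    tau_int = 1 + 2 sum rho_k, summing while the window is < c * tau_int.
    """
    x = np.asarray(samples, float)
    n = x.size
    if n < 8:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        return 1.0
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n / var
    tau = 1.0
    for w in range(1, n):
        tau = 1.0 + 2.0 * np.sum(acf[1 : w + 1])
        if w >= c * tau:
            break
    return float(max(tau, 1.0))
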