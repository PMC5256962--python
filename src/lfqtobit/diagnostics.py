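"""Heidelberger-Welch convergence screening for MCMC chains.

The diagnostic has two parts.  The stationarity test computes a
Cramer-von Mises statistic on the standardized cumulative sums of the
chain, normalized by an estimate of the spectral density at frequency
zero (autoregressive fit with the order chosen by AIC); if the full
chain rejects, the initial 10% of iterations is discarded and the test
repeated, up to 50%.  The halfwidth test then requires the relative
1.96 * sqrt(S0/n) halfwidth of the retained mean to be below ``eps``.
A chain passes the diagnostic only if both parts pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, kv

__all__ = ["heidelberger_welch", "spectrum0_ar", "pcramer", "HWResult"]


def _autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    v = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(v, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1].real / n
    return acov


def spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero from an AIC-selected AR fit.

    Yule-Walker coefficients are computed for all orders up to
    ``min(n - 1, 10 * log10(n))`` by the Levinson-Durbin recursion; the
    order minimizing ``n * log(sigma2_p) + 2p`` is kept and the spectrum
    at zero is ``sigma2_p / (1 - sum(phi))**2``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or np.ptp(x) == 0.0:
        return 0.0
    max_order = int(min(n - 1, math.floor(10.0 * math.log10(n))))
    acov = _autocovariance(x, max_order)
    if acov[0] <= 0:
        return 0.0

    sigma2 = acov[0]
    phi = np.zeros(0)
    best_aic = n * math.log(sigma2)
    best = (sigma2, phi)
    for p in range(1, max_order + 1):
        k = (acov[p] - phi @ acov[p - 1 : 0 : -1]) / sigma2 if p > 1 else acov[1] / sigma2
        phi = np.concatenate([phi - k * phi[::-1], [k]])
        sigma2 *= 1.0 - k * k
        if sigma2 <= 0:
            break
        aic = n * math.log(sigma2) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            best = (sigma2, phi.copy())
    sigma2, phi = best
    denom = (1.0 - phi.sum()) ** 2
    return float(sigma2 / denom) if denom > 0 else float("inf")


def pcramer(q: float, eps: float = 1e-5) -> float:
    """Asymptotic CDF of the Cramer-von Mises goodness-of-fit statistic."""
    if q <= 0:
        return 0.0
    log_eps = math.log(eps)
    total = 0.0
    for k in range(4):
        u = (4 * k + 1) ** 2 / (16.0 * q)
        if u > -log_eps:
            continue
        z = (
            math.exp(gammaln(k + 0.5) - gammaln(k + 1.0))
            * math.sqrt(4 * k + 1)
            / (math.pi ** 1.5 * math.sqrt(q))
        )
        total += z * math.exp(-u) * float(kv(0.25, u))
    return min(max(total, 0.0), 1.0)


@dataclass
class HWResult:
    passed: bool
    stationary: bool
    halfwidth_passed: bool
    start_index: int
    halfwidth_ratio: float
    mean: float


def heidelberger_welch(chain: np.ndarray, alpha: float = 0.05, eps: float = 0.1) -> HWResult:
    """Run the two-part Heidelberger-Welch diagnostic on a scalar chain.

    Parameters
    ----------
    chain
        Draws of one scalar quantity; length >= 100.
    alpha
        Level of the Cramer-von Mises stationarity test.
    eps
        Maximum tolerated relative halfwidth of the mean.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise ValueError("chain too short for the diagnostic (need >= 100)")
    if np.ptp(chain) == 0.0:
        # degenerate chain: stationarity is vacuous and S0 = 0
        return HWResult(True, True, True, 0, 0.0, float(chain[0]))

    stationary = False
    start = 0
    window = chain
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n)
        window = chain[start:]
        nw = len(window)
        # spectral density at zero from the second half of the retained run
        s0 = spectrum0_ar(window[nw // 2 :])
        ybar = window.mean()
        b = np.cumsum(window) - ybar * np.arange(1, nw + 1)
        if s0 <= 0:
            stationary = True
            break
        cvm = float(np.sum(b * b) / (nw * nw * s0))
        if pcramer(cvm) < 1.0 - alpha:
            stationary = True
            break
    if not stationary:
        return HWResult(False, False, False, start, float("nan"), float(window.mean()))

    ybar = float(window.mean())
    s0_kept = spectrum0_ar(window)
    halfwidth = 1.96 * math.sqrt(s0_kept / len(window))
    if halfwidth == 0.0:
        ratio = 0.0
        hw_pass = True
    elif ybar == 0.0:
        ratio = float("inf")
        hw_pass = False
    else:
        ratio = abs(halfwidth / ybar)
        hw_pass = ratio <= eps
    return HWResult(stationary and hw_pass, True, hw_pass, start, ratio, ybar)
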