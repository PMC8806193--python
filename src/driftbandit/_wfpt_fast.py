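"""Jitted first-passage log-likelihood kernel (hot path for MCMC fitting).

Same dual-series expansion as `ddm.wfpt_density`; that numpy implementation
is the reference and the two are held equal in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_NEG_INF = -1e300


@njit(cache=True, fastmath=False)
def _log_dens_lower(t: float, v: float, a: float, w: float, err_tol: float) -> float:
    """Log first-passage density at the lower bound, sigma = 1, decision time t."""
    if t <= 0.0:
        return _NEG_INF
    tt = t / (a * a)
    if tt < 1e-12:
        tt = 1e-12
    # required terms, large-time series
    if math.pi * tt * err_tol < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err_tol) / (math.pi**2 * tt))
        m = 1.0 / (math.pi * math.sqrt(tt))
        if kl < m:
            kl = m
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # required terms, small-time series
    if 2.0 * err_tol * math.sqrt(2.0 * math.pi * tt) < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err_tol * math.sqrt(2.0 * math.pi * tt)))
        m = math.sqrt(tt) + 1.0
        if ks < m:
            ks = m
    else:
        ks = 2.0
    if ks < kl:
        K = int(math.ceil(ks / 2.0)) + 1
        s = 0.0
        for k in range(-K, K + 1):
            q = w + 2.0 * k
            s += q * math.exp(-q * q / (2.0 * tt))
        f0 = s / math.sqrt(2.0 * math.pi * tt**3)
    else:
        K = int(math.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * math.exp(-(k * k) * math.pi**2 * tt / 2.0) * math.sin(
                k * math.pi * w
            )
        f0 = math.pi * s
    if f0 <= 0.0:
        return _NEG_INF
    return (
        math.log(f0)
        - 2.0 * math.log(a)
        - v * a * w
        - v * v * t / 2.0
    )


@njit(cache=True, fastmath=False)
def wfpt_loglike_fast(
    t: np.ndarray,
    resp: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    w: float,
    err_tol: float,
) -> float:
    """Summed log density over trials; decision times t (t_r already removed)."""
    total = 0.0
    for i in range(t.size):
        vi = v[i]
        wi = w
        if resp[i] == 1:  # upper boundary via start-point reflection
            vi = -vi
            wi = 1.0 - w
        ld = _log_dens_lower(t[i], vi, a[i], wi, err_tol)
        if ld <= _NEG_INF:
            return _NEG_INF
        total += ld
    return total
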