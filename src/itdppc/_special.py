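"""Log-space regularized incomplete gamma functions.

The marginalized observer needs log P(X <= x) and log P(X >= x) for
Gamma-distributed X with shape T/2 (hundreds at the longest stimulus
durations). Deep in the tails the regularized incomplete gamma underflows to
zero in double precision, so the direct ``log(gammainc(...))`` route is
supplemented with series/asymptotic evaluations that stay finite down to
log-probabilities of order -1e5.
"""

from __future__ import annotations

import numpy as np
from scipy import special as sc

# below this, log(gammainc) loses accuracy / underflows
_UNDERFLOW = 1e-280


def log_gammainc_lower(s: float, x: np.ndarray) -> np.ndarray:
    """log of the regularized lower incomplete gamma P(s, x), elementwise.

    Valid for s > 0 and x >= 0. Returns -inf at x = 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    pos = x > 0
    with np.errstate(divide="ignore"):
        p = sc.gammainc(s, np.where(pos, x, 1.0))
        direct = pos & (p > _UNDERFLOW)
        out[direct] = np.log(p[direct])
    small = pos & ~direct
    if np.any(small):
        out[small] = _log_lower_series(s, x[small])
    return out


def _log_lower_series(s: float, x: np.ndarray) -> np.ndarray:
    # P(s,x) = x^s e^-x / Gamma(s+1) * sum_k prod_{j<=k} x/(s+j)
    # converges quickly for x < s + 1, the only regime where the direct
    # evaluation underflows (the lower tail).
    term = np.ones_like(x)
    total = np.ones_like(x)
    for k in range(1, 2000):
        term = term * x / (s + k)
        total += term
        if np.max(term) < 1e-17 * np.min(total):
            break
    return s * np.log(x) - x - sc.gammaln(s + 1) + np.log(total)


def log_gammaincc(s: float, x: np.ndarray) -> np.ndarray:
    """log of the regularized upper incomplete gamma Q(s, x), elementwise.

    Valid for s > 0; returns 0 for x <= 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape)
    pos = x > 0
    with np.errstate(divide="ignore"):
        q = sc.gammaincc(s, np.where(pos, x, 1.0))
        direct = pos & (q > _UNDERFLOW)
        out[direct] = np.log(q[direct])
    large = pos & ~direct
    if np.any(large):
        out[large] = _log_upper_asymptotic(s, x[large])
    return out


def _log_upper_asymptotic(s: float, x: np.ndarray) -> np.ndarray:
    # Q(s,x) ~ x^(s-1) e^-x / Gamma(s) * [1 + (s-1)/x + (s-1)(s-2)/x^2 + ...]
    # for x >> s, the only regime where the direct evaluation underflows.
    term = np.ones_like(x)
    total = np.ones_like(x)
    for k in range(1, 60):
        term = term * (s - k) / x
        total += term
        if np.max(np.abs(term)) < 1e-17:
            break
    total = np.maximum(total, 1e-300)
    return (s - 1) * np.log(x) - x - sc.gammaln(s) + np.log(total)
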