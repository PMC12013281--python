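"""Numba kernels for the Wiener diffusion first-passage-time density.

The two-boundary Wiener process with unit diffusion coefficient, drift
``v``, boundary separation ``a`` and relative starting point ``w``
(measured from the lower boundary) admits a defective first-passage-time
density at each boundary.  Two series expansions exist — one that
converges quickly for small times and one for large times — and the
number of required terms for a target truncation error can be bounded in
closed form, so the evaluator switches automatically to whichever series
is cheaper at the requested point.

All functions here work on *decision time* (nondecision time already
subtracted by the caller) and use the ``scale = 1`` convention.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: truncation error bound for the series
_ERR = 1e-12
#: log-likelihood stand-in for impossible data (acts as -inf but keeps arithmetic finite)
NEG_INF = -1e300


@njit(cache=True)
def _fpt_norm_lower(tn: float, w: float) -> float:
    """Density of the normalized process (a=1, v=0) at the lower boundary.

    ``tn`` is time in units of a**2.  Chooses the small-time or
    large-time series by comparing the number of terms each needs for
    truncation error ``_ERR``.
    """
    if tn <= 0.0:
        return 0.0
    # number of terms for the small-time series
    if 2.0 * math.sqrt(2.0 * math.pi * tn) * _ERR < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tn * math.log(2.0 * _ERR * math.sqrt(2.0 * math.pi * tn)))
        ks = max(ks, math.sqrt(tn) + 1.0)
    else:
        ks = 2.0
    # number of terms for the large-time series
    if math.pi * tn * _ERR < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tn * _ERR) / (math.pi * math.pi * tn))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tn)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tn))

    if ks < kl:
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + ((K - 1) % 2) + 1):
            x = w + 2.0 * k
            acc += x * math.exp(-x * x / (2.0 * tn))
        return acc / math.sqrt(2.0 * math.pi * tn * tn * tn)
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * tn / 2.0) * math.sin(k * math.pi * w)
    return math.pi * acc


@njit(cache=True)
def pdf(t: float, a: float, v: float, w: float, upper: bool) -> float:
    """Defective FPT density at the given boundary, decision time ``t``."""
    if t <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return 0.0
    if upper:
        w_ = 1.0 - w
        v_ = -v
    else:
        w_ = w
        v_ = v
    base = _fpt_norm_lower(t / (a * a), w_)
    if base <= 0.0:
        return 0.0
    return base * math.exp(-v_ * a * w_ - v_ * v_ * t / 2.0) / (a * a)


@njit(cache=True)
def logpdf(t: float, a: float, v: float, w: float, upper: bool) -> float:
    p = pdf(t, a, v, w, upper)
    if p <= 0.0:
        return NEG_INF
    return math.log(p)


@njit(cache=True)
def pdf_array(t: np.ndarray, a: float, v: float, w: float, upper: bool) -> np.ndarray:
    out = np.empty(t.shape[0])
    for i in range(t.shape[0]):
        out[i] = pdf(t[i], a, v, w, upper)
    return out


@njit(cache=True)
def prob_upper(a: float, v: float, w: float) -> float:
    """Probability of absorption at the upper boundary (closed form)."""
    if v == 0.0:
        return w
    x = -2.0 * v * a
    # (1 - exp(-2 v a w)) / (1 - exp(-2 v a)), written stably
    num = math.expm1(x * w)
    den = math.expm1(x)
    return num / den


@njit(cache=True)
def trialset_loglik(
    t: np.ndarray,
    upper: np.ndarray,
    motor_regular: np.ndarray,
    a: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    t0: np.ndarray,
    xi: np.ndarray,
) -> float:
    """Summed log density over trials with per-trial parameters.

    ``t`` holds observed response times in seconds; the effective
    nondecision time ``t0 -/+ xi/2`` (motor-regular responses get the
    fast branch) is subtracted before the density is evaluated.  Returns
    ``NEG_INF`` if any trial is impossible under its parameters.
    """
    total = 0.0
    for i in range(t.shape[0]):
        if motor_regular[i]:
            nd = t0[i] - xi[i] / 2.0
        else:
            nd = t0[i] + xi[i] / 2.0
        if nd < 0.0:
            return NEG_INF
        td = t[i] - nd
        if td <= 0.0:
            return NEG_INF
        lp = logpdf(td, a[i], v[i], w[i], upper[i])
        if lp <= NEG_INF:
            return NEG_INF
        total += lp
    return total


@njit(cache=True)
def simulate_paths_euler(
    n: int, a: float, v: float, w: float, dt: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate decision times by Euler-Maruyama random walks.

    Independent of the density code; used as a cross-check oracle.
    Returns (decision_times, upper_flags).
    """
    np.random.seed(seed)
    times = np.empty(n)
    uppers = np.zeros(n, dtype=np.bool_)
    sq = math.sqrt(dt)
    for i in range(n):
        x = w * a
        t = 0.0
        while True:
            x += v * dt + sq * np.random.normal()
            t += dt
            if x >= a:
                uppers[i] = True
                break
            if x <= 0.0:
                break
        times[i] = t
    return times, uppers
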