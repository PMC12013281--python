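"""Extended Wiener drift-diffusion model of a single SRTT decision.

On every trial, noisy evidence accumulates between two boundaries at
drift rate ``delta``; the boundary separation ``alpha`` captures
response caution, the relative starting point ``beta`` captures
pre-stimulus response bias, and the nondecision time ``theta`` captures
stimulus detection/encoding and motor execution.  A response-competition
offset ``xi`` splits the nondecision time between motor-regular and
motor-nonregular executed responses: motor-regular responses take
``theta - xi/2``, motor-nonregular ones ``theta + xi/2``, so positive
``xi`` means regular responses are executed faster.

Boundary semantics follow *regularity coding* by default: the upper
boundary is the sequence-predicted (regular) response, the lower
boundary the alternative.  The diffusion coefficient is fixed at 1.

The optional inter-trial variabilities (``sv``: normal SD of the drift,
``szr``: uniform range of the starting point, ``st0``: uniform range of
the nondecision time) are integrated out by Gauss-Hermite respectively
Gauss-Legendre quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from . import wiener

__all__ = [
    "DiffusionParams",
    "TrialOutcome",
    "LoglikResult",
    "effective_nondecision",
    "fpt_density",
    "choice_probability",
    "sample_trial",
    "sample_decision_times",
    "loglik_trialset",
]

UPPER = "upper"
LOWER = "lower"

_GH_NODES = 15
_GL_NODES = 11


@dataclass(frozen=True)
class DiffusionParams:
    """Parameter vector for one experimental cell.

    alpha : boundary separation (evidence units, > 0)
    beta : relative starting point in (0, 1), measured from the lower boundary
    delta : drift rate (evidence / s), positive toward the upper boundary
    theta : mean nondecision time (s)
    xi : response-competition nondecision offset (s, signed)
    sv, szr, st0 : optional inter-trial variabilities (default 0)
    """

    alpha: float
    beta: float = 0.5
    delta: float = 0.0
    theta: float = 0.0
    xi: float = 0.0
    sv: float = 0.0
    szr: float = 0.0
    st0: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.theta < abs(self.xi) / 2.0:
            raise ValueError("theta must be at least |xi|/2")
        if min(self.sv, self.szr, self.st0) < 0.0:
            raise ValueError("inter-trial variabilities must be nonnegative")
        if self.scale != 1.0:
            raise NotImplementedError("only the scale=1 convention is implemented")

    @property
    def has_variability(self) -> bool:
        return self.sv > 0.0 or self.szr > 0.0 or self.st0 > 0.0

    def replace(self, **kwargs) -> "DiffusionParams":
        return replace(self, **kwargs)


class TrialOutcome(NamedTuple):
    decision_time: float
    boundary: str  # "upper" or "lower"
    rt: float  # decision_time + effective nondecision time


class LoglikResult(NamedTuple):
    value: float
    impossible: bool


def effective_nondecision(theta: float, xi: float, motor_regular: bool) -> float:
    """Nondecision time of an executed response: theta -/+ xi/2."""
    if theta < abs(xi) / 2.0:
        raise ValueError("theta must be at least |xi|/2")
    return theta - xi / 2.0 if motor_regular else theta + xi / 2.0


def _boundary_flag(boundary: str) -> bool:
    if boundary == UPPER:
        return True
    if boundary == LOWER:
        return False
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def _quadrature(params: DiffusionParams):
    """(weight, delta, beta, t0_shift) nodes integrating out the variabilities."""
    nodes = [(1.0, params.delta, params.beta, 0.0)]
    if params.sv > 0.0:
        x, w_ = np.polynomial.hermite_e.hermegauss(_GH_NODES)
        w_ = w_ / w_.sum()
        nodes = [(wi * w, params.delta + xi_ * params.sv, b, s)
                 for (w, d, b, s) in nodes for xi_, wi in zip(x, w_)]
    if params.szr > 0.0:
        x, w_ = np.polynomial.legendre.leggauss(_GL_NODES)
        w_ = w_ / w_.sum()
        nodes = [(wi * w, d, b + 0.5 * xi_ * params.szr, s)
                 for (w, d, b, s) in nodes for xi_, wi in zip(x, w_)]
    if params.st0 > 0.0:
        x, w_ = np.polynomial.legendre.leggauss(_GL_NODES)
        w_ = w_ / w_.sum()
        nodes = [(wi * w, d, b, s + 0.5 * xi_ * params.st0)
                 for (w, d, b, s) in nodes for xi_, wi in zip(x, w_)]
    return nodes


def fpt_density(
    t: float | np.ndarray,
    params: DiffusionParams,
    boundary: str,
    motor_regular: bool | None = None,
) -> float | np.ndarray:
    """Defective density of observed RT ``t`` (s) at the given boundary.

    ``t`` includes the effective nondecision time; the density is zero
    at or below it.  Under regularity coding the upper boundary is the
    motor-regular response, so ``motor_regular`` defaults to
    ``boundary == "upper"``.
    """
    up = _boundary_flag(boundary)
    if motor_regular is None:
        motor_regular = up
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for weight, d, b, shift in _quadrature(params):
        nd = effective_nondecision(params.theta, params.xi, motor_regular) + shift
        td = t_arr - nd
        mask = td > 0.0
        if not 0.0 < b < 1.0:
            continue
        if mask.any():
            out[mask] += weight * wiener.pdf_array(td[mask], params.alpha, d, b, up)
    return out if np.ndim(t) else float(out[0])


def choice_probability(params: DiffusionParams) -> float:
    """Probability that the process is absorbed at the upper boundary."""
    total = 0.0
    for weight, d, b, _ in _quadrature(params):
        total += weight * wiener.prob_upper(params.alpha, d, b)
    return float(total)


def _density_grid(params: DiffusionParams, n_grid: int = 4096):
    """Decision-time grid with both defective densities, for CDF inversion."""
    # expand the horizon until the two defective densities integrate to ~1
    base = DiffusionParams(
        alpha=params.alpha, beta=params.beta, delta=params.delta, theta=0.0,
        sv=params.sv, szr=params.szr, st0=0.0,
    )
    t_max = 4.0 * params.alpha**2
    for _ in range(40):
        t = np.linspace(0.0, t_max, n_grid)
        fu = fpt_density(t, base, UPPER)
        fl = fpt_density(t, base, LOWER)
        mass = np.trapezoid(fu + fl, t)
        if mass > 1.0 - 1e-7 and fu[-1] + fl[-1] < 1e-10:
            break
        t_max *= 1.6
    return t, fu, fl


def sample_decision_times(
    params: DiffusionParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (decision_time, upper) pairs by inverting the FPT CDF.

    Exact up to the grid resolution of the tabulated density; the Euler
    path simulator in :mod:`srtddm.wiener` provides an independent
    cross-check.
    """
    t, fu, fl = _density_grid(params)
    cu = np.concatenate([[0.0], np.cumsum((fu[1:] + fu[:-1]) / 2.0 * np.diff(t))])
    cl = np.concatenate([[0.0], np.cumsum((fl[1:] + fl[:-1]) / 2.0 * np.diff(t))])
    p_up = cu[-1] / (cu[-1] + cl[-1])
    upper = rng.random(n) < p_up
    times = np.empty(n)
    for flag, c in ((True, cu), (False, cl)):
        m = upper == flag
        if not m.any():
            continue
        u = rng.random(int(m.sum())) * c[-1]
        times[m] = np.interp(u, c, t)
    if params.st0 > 0.0:
        times += rng.uniform(-params.st0 / 2.0, params.st0 / 2.0, size=n)
    return times, upper


def sample_trial(
    params: DiffusionParams,
    rng: np.random.Generator,
    upper_is_motor_regular: bool = True,
) -> TrialOutcome:
    """Sample one trial; the RT includes the effective nondecision time."""
    times, uppers = sample_decision_times(params, 1, rng)
    up = bool(uppers[0])
    motor_regular = up == upper_is_motor_regular
    nd = effective_nondecision(params.theta, params.xi, motor_regular)
    return TrialOutcome(float(times[0]), UPPER if up else LOWER, float(times[0]) + nd)


def loglik_trialset(
    trials: Sequence[tuple[float, str, bool]] | np.ndarray,
    params: DiffusionParams,
) -> LoglikResult:
    """Joint log-likelihood of (rt, boundary, motor_regular) trials.

    RTs are in seconds.  Impossible data (an RT at or below its
    effective nondecision time, or otherwise of zero density) yields
    ``LoglikResult(-inf, impossible=True)`` instead of raising.
    """
    rts = np.array([tr[0] for tr in trials], dtype=float)
    uppers = np.array([_boundary_flag(tr[1]) for tr in trials])
    motor = np.array([bool(tr[2]) for tr in trials])
    if not params.has_variability:
        n = len(rts)
        fill = np.full(n, 1.0)
        value = wiener.trialset_loglik(
            rts, uppers, motor,
            fill * params.alpha, fill * params.delta, fill * params.beta,
            fill * params.theta, fill * params.xi,
        )
        if value <= wiener.NEG_INF:
            return LoglikResult(-np.inf, True)
        return LoglikResult(float(value), False)
    total = 0.0
    for rt, up, mo in zip(rts, uppers, motor):
        dens = fpt_density(float(rt), params, UPPER if up else LOWER, motor_regular=bool(mo))
        if dens <= 0.0:
            return LoglikResult(-np.inf, True)
        total += math.log(dens)
    return LoglikResult(total, False)
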