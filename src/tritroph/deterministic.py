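"""Mean-field rate equations of the five populations and their integration.

The right-hand side is the exact expectation of the reaction network in
the large-population limit (same-type competition differs by the usual
ordered-pair term of order 1/K).  Writing x = xI + xU and y = yI + yU:

    dxI/dt = -x xI / K - dx xI + Qx S xU z - fy xI y
    dxU/dt = gx (rx xI + xU) - x xU / K - dx xU - Qx S xU z - fy xU y
    dyI/dt = -dy yI + Qy fy xI yU
    dyU/dt = ky fy xU (rp yI + yU)
             + (re ky (1-Qy) - (1 - rp ky) Qy) fy xI yU
             + (rp re ky (1-Qy) + rp^2 ky Qy) fy xI yI
             - dy yU
    dz/dt  = -Qx S xU z + nz Qy fy xI y - dz z

With no parasite (xI = yI = z = 0) the system reduces to a damped
Lotka-Volterra predator-prey model with stable focus
(xU*, yU*) = (dy/(ky fy), (gx - dx - xU*/K)/fy).

Integration uses LSODA (adaptive, stiff-capable) at tight tolerances:
the cyclic regimes pass through deep abundance valleys (values far below
one individual) that the extinction classifier reads, so sloppy
tolerances would move phase-map boundaries.  Components are clamped to
zero before each right-hand-side evaluation and in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .model import STATE_VARS, Params, SystemState, Trajectory

__all__ = ["rhs", "integrate", "long_run_summary", "TailSummary", "IntegrationError"]


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time t={last_time:g})")
        self.last_time = last_time


@njit(cache=True)
def _rhs_core(s, gx, rx, dx, K, S, Qx, nz, dz, fy, ky, Qy, rp, re_, dy):
    xU, xI, yU, yI, z = s[0], s[1], s[2], s[3], s[4]
    x = xI + xU
    y = yI + yU
    out = np.empty(5)
    out[0] = gx * (rx * xI + xU) - x * xU / K - dx * xU - Qx * S * xU * z - fy * xU * y
    out[1] = -x * xI / K - dx * xI + Qx * S * xU * z - fy * xI * y
    out[2] = (ky * fy * xU * (rp * yI + yU)
              + (re_ * ky * (1.0 - Qy) - (1.0 - rp * ky) * Qy) * fy * xI * yU
              + (rp * re_ * ky * (1.0 - Qy) + rp * rp * ky * Qy) * fy * xI * yI
              - dy * yU)
    out[3] = -dy * yI + Qy * fy * xI * yU
    out[4] = -Qx * S * xU * z + nz * Qy * fy * xI * y - dz * z
    return out


def _param_tuple(p: Params):
    return (p.gx, p.rx, p.dx, p.K, p.S, p.Qx, float(p.nz), p.dz,
            p.fy, p.ky, p.Qy, p.rp, p.re, p.dy)


def rhs(state, p: Params) -> np.ndarray:
    """Time derivative over ``(xU, xI, yU, yI, z)`` at a nonnegative state.

    Raises ``ValueError`` on any negative component — the integrator is
    responsible for clamping before calling.
    """
    s = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if np.any(s < 0):
        raise ValueError("rhs requires a componentwise nonnegative state")
    return _rhs_core(s, *_param_tuple(p))


def integrate(
    s0: SystemState,
    p: Params,
    t_max: float = 2000.0,
    sample_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the rate equations and sample on a uniform grid.

    Any component that drifts below zero by floating error is clamped to
    zero (both inside the right-hand side and in the returned states).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    pt = _param_tuple(p)

    def f(s, _t):
        return _rhs_core(np.maximum(s, 0.0), *pt)

    t_grid = np.arange(0.0, t_max + 0.5 * sample_dt, sample_dt)
    if t_grid[-1] > t_max:
        t_grid = t_grid[:-1]
    if t_grid[-1] < t_max:
        t_grid = np.append(t_grid, t_max)
    sol, info = odeint(
        f, s0.to_array(), t_grid, rtol=rtol, atol=atol,
        full_output=True, mxstep=100_000_000, printmessg=False,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(info["message"], float(np.atleast_1d(info["tcur"])[-1]))
    np.clip(sol, 0.0, None, out=sol)
    return Trajectory(times=t_grid, states=sol, engine="deterministic", params=p)


@dataclass(frozen=True)
class TailSummary:
    """Time-averaged abundances and minima over a trailing time window."""

    t_start: float
    t_end: float
    mean: dict
    min: dict

    def mean_array(self) -> np.ndarray:
        return np.array([self.mean[v] for v in STATE_VARS])


def long_run_summary(traj: Trajectory, tail_fraction: float = 0.2) -> TailSummary:
    """Mean and minimum of each population over the final window.

    The window covers the last ``tail_fraction`` of the trajectory's time
    span; means are time-weighted (trapezoid rule), so they are correct
    on non-uniform grids too.  For cyclic or chaotic runs this is the
    natural summary the outcome classifier reads.
    """
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must lie in (0, 1]")
    t = traj.times
    if t.size == 0:
        raise ValueError("empty trajectory")
    if t.size == 1:
        vals = dict(zip(STATE_VARS, map(float, traj.states[0])))
        return TailSummary(float(t[0]), float(t[0]), vals, dict(vals))
    t0 = t[-1] - tail_fraction * (t[-1] - t[0])
    k = int(np.searchsorted(t, t0))
    k = min(k, t.size - 2)  # keep at least two samples in the window
    tt = t[k:]
    ss = np.asarray(traj.states[k:], float)
    span = tt[-1] - tt[0]
    if span > 0:
        means = np.trapezoid(ss, tt, axis=0) / span
    else:
        means = ss.mean(axis=0)
    return TailSummary(
        t_start=float(tt[0]),
        t_end=float(tt[-1]),
        mean=dict(zip(STATE_VARS, map(float, means))),
        min=dict(zip(STATE_VARS, map(float, ss.min(axis=0)))),
    )
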