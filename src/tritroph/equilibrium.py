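"""Steady states of the rate equations and the parasite-invasion test.

Setting the five time derivatives to zero and eliminating variables
reduces the interior (all-positive) equilibrium to a single scalar
equation in the infected-prey abundance xI.  With the shorthand

    alpha = Qx S,  beta = Qy fy,  gamma = rp ky fy,  delta = ky fy,
    epsilon = (re ky (1-Qy) - (1 - rp ky) Qy) fy,
    zeta  = (rp re ky (1-Qy) + rp^2 ky Qy) fy,
    eta   = nz Qy fy,  lam = beta / dy,

and the intermediate functions

    Phi(xI)   = lam xI + 1
    Psi(xI)   = (dy - epsilon xI - zeta lam xI^2) / (gamma lam xI + delta)
    Theta(xI) = alpha Psi + dz,

xI* must be a root of

    Theta [ (xI + Psi + K dx)(K Phi Psi alpha eta xI + K Theta Phi Psi fy)
            - (K gx (rx xI + Psi) - Psi (xI + Psi + K dx))
              (K Phi Psi alpha eta - K Theta Phi fy) ] = 0

after which the remaining populations follow by back-substitution:
xU* = Psi(xI*), yI* = lam xI* yU*, z* = eta xI* (yI* + yU*) / Theta, and
yU* in either of two algebraically equivalent forms (their agreement is
used as a consistency check on every root).

Root finding is by bracketing on a log-dense scan — the scalar equation
is high-degree with sign structure inherited from the rational
intermediates, so bracketing is robust where closed-form factoring is
not.  A candidate root is accepted only if all five back-substituted
abundances are strictly positive and the full five-equation right-hand
side vanishes at the point (max-norm below ``rhs_tol``): the scalar
equation proposes, the rate equations decide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .deterministic import rhs
from .model import Params, SystemState

__all__ = [
    "DerivedCoefficients",
    "EquilibriumPoint",
    "PoleError",
    "PredatorNotViableError",
    "derived_coefficients",
    "polynomial_residual",
    "solve_interior_equilibria",
    "parasite_free_equilibrium",
    "invasion_growth_rate",
]


class PoleError(ArithmeticError):
    """The scalar equilibrium equation hit a pole of an intermediate."""


class PredatorNotViableError(ValueError):
    """The predator cannot persist even without the parasite."""


@dataclass(frozen=True)
class DerivedCoefficients:
    """Composite rate coefficients of the equilibrium reduction.

    All are nonnegative except ``epsilon``, which is negative whenever
    the infected-prey encounter drains uninfected predators faster than
    exposed reproduction replaces them.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float
    zeta: float
    eta: float
    lam: float


def derived_coefficients(p: Params) -> DerivedCoefficients:
    return DerivedCoefficients(
        alpha=p.Qx * p.S,
        beta=p.Qy * p.fy,
        gamma=p.rp * p.ky * p.fy,
        delta=p.ky * p.fy,
        epsilon=(p.re * p.ky * (1 - p.Qy) - (1 - p.rp * p.ky) * p.Qy) * p.fy,
        zeta=(p.rp * p.re * p.ky * (1 - p.Qy) + p.rp**2 * p.ky * p.Qy) * p.fy,
        eta=p.nz * p.Qy * p.fy,
        lam=p.Qy * p.fy / p.dy,
    )


@dataclass(frozen=True)
class EquilibriumPoint:
    """A steady state with residual diagnostics.

    ``residual`` is the max-norm of the rate equations at the point;
    ``stable_hint`` records whether dynamical convergence to the point
    has been observed ("converged_to") or not assessed.
    """

    xU: float
    xI: float
    yU: float
    yI: float
    z: float
    residual: float
    stable_hint: str = "not_assessed"

    def to_array(self) -> np.ndarray:
        return np.array([self.xU, self.xI, self.yU, self.yI, self.z])

    @property
    def is_interior(self) -> bool:
        return bool(np.all(self.to_array() > 0))


def _intermediates(xI: float, p: Params, c: DerivedCoefficients):
    den = c.gamma * c.lam * xI + c.delta
    if den == 0 or not np.isfinite(den):
        raise PoleError(f"Psi pole at xI={xI!r}")
    psi = (p.dy - c.epsilon * xI - c.zeta * c.lam * xI**2) / den
    phi = c.lam * xI + 1.0
    theta = c.alpha * psi + p.dz
    return phi, psi, theta


def polynomial_residual(xI: float, p: Params) -> float:
    """The scalar equilibrium equation's left-hand side at ``xI``.

    Zero exactly at candidate interior equilibria.  Raises
    :class:`PoleError` where an intermediate blows up (treated as a scan
    interval boundary by the solver).
    """
    if xI <= 0:
        raise ValueError("xI must be positive")
    c = derived_coefficients(p)
    phi, psi, theta = _intermediates(xI, p, c)
    K, dx, gx, rx, fy = p.K, p.dx, p.gx, p.rx, p.fy
    a = xI + psi + K * dx
    val = theta * (
        a * (K * phi * psi * c.alpha * c.eta * xI + K * theta * phi * psi * fy)
        - (K * gx * (rx * xI + psi) - psi * a)
        * (K * phi * psi * c.alpha * c.eta - K * theta * phi * fy)
    )
    if not np.isfinite(val):
        raise PoleError(f"non-finite residual at xI={xI!r}")
    return float(val)


def _back_substitute(xI: float, p: Params, c: DerivedCoefficients):
    """Remaining populations at a root, via both printed yU forms."""
    phi, psi, theta = _intermediates(xI, p, c)
    xU = psi
    K, dx, gx, rx, fy = p.K, p.dx, p.gx, p.rx, p.fy
    den1 = K * phi * c.alpha * c.eta * xU - K * theta * phi * fy
    den2 = K * phi * c.alpha * c.eta * xI * xU + K * theta * phi * fy * xU
    if den1 == 0 or den2 == 0:
        raise PoleError(f"yU denominator vanishes at xI={xI!r}")
    yU1 = theta * (xI + xU + K * dx) / den1
    yU2 = (K * theta * gx * (rx * xI + xU) - theta * (xI + xU + K * dx) * xU) / den2
    yI = c.lam * xI * yU1
    if theta == 0:
        raise PoleError(f"Theta vanishes at xI={xI!r}")
    z = c.eta * xI * (yI + yU1) / theta
    return xU, yU1, yU2, yI, z


def solve_interior_equilibria(
    p: Params,
    n_scan: int = 4000,
    xI_min: float = 1e-6,
    rhs_tol: float = 1e-6,
    yu_agreement_rtol: float = 1e-6,
) -> list:
    """All interior steady states found in ``xI in (0, K]``.

    Scans a log-dense grid for sign changes of the scalar equation
    (poles split the scan into separate intervals), polishes each
    bracketed root with Brent's method, back-substitutes the remaining
    populations, and keeps only points where all five abundances are
    positive, both yU forms agree, and the full right-hand side vanishes
    to ``rhs_tol``.  An empty list is a valid outcome: no three-species
    equilibrium exists (e.g. whenever Qx, Qy or ky is zero).
    """
    c = derived_coefficients(p)
    if c.eta == 0 or c.alpha == 0 or p.ky == 0:
        return []  # no parasite production or no predator reproduction
    xs = np.geomspace(xI_min, p.K, n_scan)
    vals = np.full(n_scan, np.nan)
    for k, x in enumerate(xs):
        try:
            vals[k] = polynomial_residual(x, p)
        except PoleError:
            pass  # NaN marks a scan-interval boundary
    points: list[EquilibriumPoint] = []
    for k in range(n_scan - 1):
        v0, v1 = vals[k], vals[k + 1]
        if not (np.isfinite(v0) and np.isfinite(v1)):
            continue
        if v0 == 0.0:
            root = xs[k]
        elif v0 * v1 < 0:
            root = brentq(lambda x: polynomial_residual(x, p),
                          xs[k], xs[k + 1], xtol=1e-14, rtol=8.9e-16)
        else:
            continue
        try:
            xU, yU1, yU2, yI, z = _back_substitute(root, p, c)
        except PoleError:
            continue
        comps = np.array([xU, root, yU1, yI, z])
        if not np.all(np.isfinite(comps)) or np.any(comps <= 0):
            continue
        if abs(yU1 - yU2) > yu_agreement_rtol * max(abs(yU1), abs(yU2)):
            continue  # spurious root introduced by clearing denominators
        res = float(np.max(np.abs(rhs(comps, p))))
        if res < rhs_tol:
            points.append(EquilibriumPoint(
                xU=xU, xI=float(root), yU=yU1, yI=yI, z=z, residual=res))
    # drop duplicates from adjacent brackets hitting the same root
    unique: list[EquilibriumPoint] = []
    for pt in points:
        if not any(abs(pt.xI - q.xI) <= 1e-8 * max(pt.xI, q.xI) for q in unique):
            unique.append(pt)
    return unique


def parasite_free_equilibrium(p: Params) -> EquilibriumPoint:
    """The damped Lotka-Volterra steady state with no parasite.

    xU* = dy / (ky fy), yU* = (gx - dx - xU*/K) / fy, all infected and
    free-living parasite compartments zero.  Requires the predator to be
    viable (yU* > 0).
    """
    if p.ky == 0:
        raise PredatorNotViableError("ky = 0: the predator cannot reproduce")
    xU = p.dy / (p.ky * p.fy)
    yU = (p.gx - p.dx - xU / p.K) / p.fy
    if yU <= 0:
        raise PredatorNotViableError(
            f"gx - dx - dy/(ky fy K) = {p.gx - p.dx - xU / p.K:g} <= 0"
        )
    res = float(np.max(np.abs(rhs(np.array([xU, 0.0, yU, 0.0, 0.0]), p))))
    return EquilibriumPoint(xU=xU, xI=0.0, yU=yU, yI=0.0, z=0.0, residual=res)


def invasion_growth_rate(p: Params, h: float = 1e-6) -> float:
    """Dominant growth rate of a rare parasite at the parasite-free state.

    Linearizes the infected/parasite subsystem (xI, yI, z) around the
    parasite-free equilibrium by central finite differences of the full
    right-hand side and returns the largest real part of the 3x3 Jacobian
    block's eigenvalues.  Positive means the parasite invades.
    """
    pf = parasite_free_equilibrium(p)
    s = pf.to_array()
    idx = [1, 3, 4]  # xI, yI, z in canonical (xU, xI, yU, yI, z) order
    J = np.empty((3, 3))
    for col, j in enumerate(idx):
        sp = s.copy()
        sp[j] += h
        fp = rhs(sp, p)
        sm = s.copy()
        sm[j] = max(sm[j] - h, 0.0)
        fm = rhs(sm, p)
        J[:, col] = (fp[idx] - fm[idx]) / (sp[j] - sm[j])
    return float(np.max(np.linalg.eigvals(J).real))


def equilibrium_report(p: Params) -> dict:
    """JSON-friendly summary: interior equilibria, parasite-free point,
    invasion growth rate."""
    report: dict = {"interior_equilibria": [], "parasite_free": None,
                    "invasion_growth_rate": None}
    for pt in solve_interior_equilibria(p):
        report["interior_equilibria"].append({
            "xU": pt.xU, "xI": pt.xI, "yU": pt.yU, "yI": pt.yI, "z": pt.z,
            "residual": pt.residual,
        })
    try:
        pf = parasite_free_equilibrium(p)
    except PredatorNotViableError as err:
        report["parasite_free"] = {"error": str(err)}
    else:
        report["parasite_free"] = {"xU": pf.xU, "yU": pf.yU, "residual": pf.residual}
        report["invasion_growth_rate"] = invasion_growth_rate(p)
    return report
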