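"""Phase-boundary thresholds under the reference study conditions.

Each function here locates one boundary of the deterministic phase maps
built from the reference parameter set: the minimal infection
probabilities permitting three-species coexistence, and the edges of the
composition regions (which host subpopulation, infected or uninfected,
dominates).  All protocols share the same classification settings —
integrate the rate equations to t = 2000 from the reference initial
abundances, average the final 20% of the run, and call a species extinct
below a tail-mean total abundance of one individual — and refine each
boundary by bisection to a parameter tolerance of 0.005.

Region edges that are minima over a 2-D plane are located by scanning
rows (or columns) of the plane at moderate resolution, bisecting the
boundary within each row, and taking the minimum over rows; the printed
maps justify the scan windows used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deterministic import integrate
from .model import REFERENCE_INITIAL_STATE, Params, SystemState, make_params
from .phase import Coexistence, Composition, OutcomeLabel, classify, _as_predicate

__all__ = ["ThresholdRunner", "compute_reference_thresholds", "THRESHOLD_PROTOCOLS"]


@dataclass
class ThresholdRunner:
    """Deterministic classify-at-parameters engine with a run cache.

    The cache matters because the scans of different boundaries revisit
    the same parameter cells (e.g. the infected-prey-dominant band scan
    feeds two different region edges).
    """

    base: Params = field(default_factory=make_params)
    state0: SystemState = REFERENCE_INITIAL_STATE
    t_max: float = 2000.0
    sample_dt: float = 0.1
    extinction_threshold: float = 1.0
    tail_fraction: float = 0.2
    tol: float = 0.005

    def __post_init__(self) -> None:
        self._cache: dict = {}

    def label(self, **overrides) -> OutcomeLabel:
        p = self.base.replace(**overrides)
        key = tuple(sorted(p.to_dict().items()))
        if key not in self._cache:
            traj = integrate(self.state0, p, t_max=self.t_max,
                             sample_dt=self.sample_dt)
            self._cache[key] = classify(traj, self.extinction_threshold,
                                        self.tail_fraction)
        return self._cache[key]

    # -- 1-D boundary machinery -------------------------------------------
    def first_true(self, axis: str, predicate, scan, fixed: dict):
        """Smallest scanned value where ``predicate`` holds, bisected
        against the preceding (false) scan point; None if never true."""
        pred = _as_predicate(predicate)
        scan = np.asarray(scan, float)
        prev = None
        for v in scan:
            if pred(self.label(**fixed, **{axis: float(v)})):
                if prev is None:
                    return float(v)  # true already at the scan edge
                return self.bisect(axis, predicate, prev, float(v), fixed)
            prev = float(v)
        return None

    def bisect(self, axis: str, predicate, lo: float, hi: float, fixed: dict):
        """Boundary between a false ``lo`` and a true ``hi`` to ``tol``."""
        pred = _as_predicate(predicate)
        while hi - lo > self.tol:
            mid = 0.5 * (lo + hi)
            if pred(self.label(**fixed, **{axis: mid})):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def min_over_rows(self, axis: str, predicate, scan, other_axis: str,
                      other_values, fixed: dict | None = None):
        """Minimum boundary value of ``axis`` over rows of a plane."""
        fixed = dict(fixed or {})
        best = None
        for o in np.asarray(other_values, float):
            v = self.first_true(axis, predicate, scan,
                                {**fixed, other_axis: float(o)})
            if v is not None and (best is None or v < best):
                best = v
        return best


# ---------------------------------------------------------------------------
# The individual boundary protocols (no reproductive costs unless the
# protocol itself varies a cost factor; the runner's base is the
# reference set with rp = rx = re = 1, Qx = Qy = 1).

def coexistence_threshold_Qy(r: ThresholdRunner) -> float:
    """Minimal predator infection probability for three-species
    coexistence at maximal prey infection probability."""
    return r.bisect("Qy", Coexistence.ALL_THREE, 0.05, 0.9, {"Qx": 1.0})


def coexistence_threshold_Qx(r: ThresholdRunner) -> float:
    """Minimal prey infection probability for three-species coexistence
    at maximal predator infection probability."""
    return r.bisect("Qx", Coexistence.ALL_THREE, 0.01, 0.5, {"Qy": 1.0})


def min_Qx_both_infected(r: ThresholdRunner) -> float:
    """Left edge of the region where infected individuals dominate both
    host populations, over the (Qx, Qy) plane."""
    return r.min_over_rows("Qx", Composition.BOTH_INFECTED,
                           np.arange(0.10, 1.0001, 0.1),
                           "Qy", [0.4, 0.5, 0.6, 0.8, 1.0])


def min_Qy_both_infected(r: ThresholdRunner) -> float:
    """Lower edge of the both-infected-dominant region over the
    (Qx, Qy) plane."""
    return r.min_over_rows("Qy", Composition.BOTH_INFECTED,
                           np.arange(0.30, 0.6001, 0.05),
                           "Qx", [0.3, 0.5, 0.7, 1.0])


def min_Qy_predI_preyU(r: ThresholdRunner) -> float:
    """Lower edge in Qy of the region where infected predators dominate
    while uninfected prey dominate, over the (Qx, Qy) plane.

    The region is a diagonal band whose plane-wide Qy minimum sits at
    intermediate-to-large Qx, so the column scan spans 0.15-0.8.
    """
    return r.min_over_rows("Qy", Composition.PRED_I_PREY_U,
                           np.arange(0.30, 0.7001, 0.025),
                           "Qx", np.arange(0.15, 0.8001, 0.05))


def min_Qx_predI_preyU_at_Qy1(r: ThresholdRunner) -> float:
    """Lower Qx edge of the infected-predator/uninfected-prey band at
    maximal predator infection probability."""
    return r.first_true("Qx", Composition.PRED_I_PREY_U,
                        np.arange(0.06, 0.3001, 0.02), {"Qy": 1.0})


def _predU_preyI_band_at_Qx1(r: ThresholdRunner):
    """Qy scan of the infected-prey/uninfected-predator outcome at
    Qx = 1, rp = 1 (cached; shared by two protocols)."""
    scan = np.arange(0.20, 0.6001, 0.02)
    pred = _as_predicate(Composition.PRED_U_PREY_I)
    flags = [pred(r.label(Qx=1.0, Qy=float(v))) for v in scan]
    return scan, flags


def min_Qy_predU_preyI_at_Qx1(r: ThresholdRunner) -> float:
    """Lower Qy edge of the infected-prey/uninfected-predator band at
    maximal prey infection probability."""
    scan, flags = _predU_preyI_band_at_Qx1(r)
    for k, flag in enumerate(flags):
        if flag:
            if k == 0:
                return float(scan[0])
            return r.bisect("Qy", Composition.PRED_U_PREY_I,
                            float(scan[k - 1]), float(scan[k]), {"Qx": 1.0})
    return None


def min_rp_predU_preyI(r: ThresholdRunner) -> float:
    """Minimal infected-predator reproduction factor rp for which the
    infected-prey/uninfected-predator outcome occurs anywhere in the
    (rp, Qy) plane at maximal prey infection probability.

    The outcome occupies a hairline diagonal sliver in Qy (width of
    order 0.002-0.005) wedged between the both-infected and
    both-uninfected regions, so each rp column is probed with a fine Qy
    scan; the rp edge of "the sliver exists in this column" is then
    bisected.
    """
    pred = _as_predicate(Composition.PRED_U_PREY_I)
    qy_scan = np.arange(0.300, 0.4001, 0.0025)

    def column_has_outcome(rp: float) -> bool:
        return any(pred(r.label(Qx=1.0, Qy=round(float(q), 4), rp=round(rp, 6)))
                   for q in qy_scan)

    rp_grid = np.arange(1.0, 0.2999, -0.025)
    last_true = None
    for rp in rp_grid:
        if column_has_outcome(float(rp)):
            last_true = float(rp)
        elif last_true is not None:
            lo, hi = float(rp), last_true
            while hi - lo > r.tol:
                mid = 0.5 * (lo + hi)
                if column_has_outcome(mid):
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)
    return last_true


#: name -> protocol function, in presentation order
THRESHOLD_PROTOCOLS = {
    "coexistence_min_Qy": coexistence_threshold_Qy,
    "coexistence_min_Qx": coexistence_threshold_Qx,
    "both_infected_min_Qx": min_Qx_both_infected,
    "both_infected_min_Qy": min_Qy_both_infected,
    "predI_preyU_min_Qy": min_Qy_predI_preyU,
    "predI_preyU_min_Qx_at_Qy1": min_Qx_predI_preyU_at_Qy1,
    "predU_preyI_min_Qy_at_Qx1": min_Qy_predU_preyI_at_Qx1,
    "predU_preyI_min_rp": min_rp_predU_preyI,
}


def compute_reference_thresholds(which=None, runner: ThresholdRunner | None = None) -> dict:
    """Run the named threshold protocols (all by default) and return
    ``{name: value}``; one shared runner caches overlapping cells."""
    r = runner or ThresholdRunner()
    names = list(THRESHOLD_PROTOCOLS) if which is None else list(which)
    return {name: THRESHOLD_PROTOCOLS[name](r) for name in names}
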