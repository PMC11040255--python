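"""Parameters, state, and the individual-level reaction network.

The system couples three species: a prey (intermediate host), a predator
(definitive host) and a trophically transmitted parasite.  Free-living
parasites infect prey on encounter; predators acquire the parasite by
consuming infected prey, whereupon the parasite reproduces and releases
``nz`` free-living offspring.  Prey and predator populations are split
into infected and uninfected subpopulations; parasite transmission is
purely trophic (no vertical transmission).

Everything downstream — the exact stochastic simulation and the
mean-field rate equations — is generated from the channel list built
here, so the two engines cannot drift apart.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_VARS",
    "PARAM_NAMES",
    "REFERENCE_PARAMS",
    "REFERENCE_INITIAL_STATE",
    "Params",
    "SystemState",
    "Reaction",
    "Trajectory",
    "ValidationError",
    "ConstraintError",
    "make_params",
    "build_reaction_network",
    "propensities",
    "mean_field_drift",
]

#: Canonical ordering of the five state variables used for every vector
#: quantity in the package (states, reaction deltas, ODE right-hand sides).
STATE_VARS = ("xU", "xI", "yU", "yI", "z")

PARAM_NAMES = (
    "gx", "rx", "dx", "K", "S", "Qx", "nz", "dz",
    "fy", "ky", "Qy", "rp", "re", "dy",
)

#: Reference parameter set (no reproductive costs, certain infection).
#: These are the package defaults; every sweep perturbs from here.
REFERENCE_PARAMS: dict = {
    "gx": 2.0,    # prey reproduction rate
    "rx": 1.0,    # reproductive cost factor on infected prey
    "dx": 0.1,    # prey intrinsic death rate
    "K": 2000.0,  # prey carrying capacity (competition scales as 1/K)
    "S": 0.0005,  # prey-parasite encounter rate per pair
    "Qx": 1.0,    # P(encounter infects the prey)
    "nz": 6,      # parasite offspring per successful predator infection
    "dz": 0.09,   # free-living parasite death rate
    "fy": 0.01,   # predation rate per prey-predator pair
    "ky": 0.2,    # predator reproduction efficiency per consumed prey
    "Qy": 1.0,    # P(consuming infected prey infects the predator)
    "rp": 1.0,    # reproductive cost factor on infected predator
    "re": 1.0,    # reproductive cost factor on exposure without infection
    "dy": 1.0,    # predator intrinsic death rate
}


class ValidationError(ValueError):
    """A parameter value is outside its admissible range."""


class ConstraintError(ValueError):
    """A cross-parameter constraint is violated (e.g. rp > re)."""


_RATES = ("gx", "dx", "S", "dz", "fy", "dy")        # strictly positive
_UNIT_INTERVAL = ("rx", "Qx", "ky", "Qy", "rp", "re")  # within [0, 1]


@dataclass(frozen=True)
class Params:
    """The 14 individual-level rates and probabilities.

    Rates are per individual (or per pair, for encounter rates) per unit
    time; ``rx``, ``rp``, ``re`` are multiplicative factors on the
    reproduction probability of infected/exposed hosts (1 = no cost,
    0 = complete cost); ``Qx``, ``Qy`` are infection probabilities.
    Infection is assumed more costly than mere exposure, so ``rp <= re``.
    """

    gx: float
    rx: float
    dx: float
    K: float
    S: float
    Qx: float
    nz: int
    dz: float
    fy: float
    ky: float
    Qy: float
    rp: float
    re: float
    dy: float

    def __post_init__(self) -> None:
        for name in _RATES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")
        for name in _UNIT_INTERVAL:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K!r}")
        if self.nz < 1 or int(self.nz) != self.nz:
            raise ValidationError(f"nz must be a positive integer, got {self.nz!r}")
        if self.rp > self.re:
            raise ConstraintError(
                f"infection cost must not be milder than exposure cost: "
                f"rp={self.rp} > re={self.re}"
            )

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **changes) -> "Params":
        """Return a new validated ``Params`` with the given fields changed."""
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    # -- flat key:value config round trip ---------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Params":
        with open(path) as fh:
            values = yaml.safe_load(fh)
        if not isinstance(values, Mapping):
            raise ValidationError(f"config {path} is not a flat key:value mapping")
        return make_params(values)


def make_params(values: Mapping[str, float] | None = None) -> Params:
    """Build a validated :class:`Params`, defaulting to the reference set.

    Parameters
    ----------
    values
        Mapping of parameter name to value; omitted parameters take the
        reference defaults.  Unknown keys raise :class:`ValidationError`.
    """
    merged = dict(REFERENCE_PARAMS)
    if values:
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        merged.update(values)
    nz = merged["nz"]
    if float(nz).is_integer():
        merged["nz"] = int(nz)
    return Params(**merged)


@dataclass(frozen=True)
class SystemState:
    """Abundances of the five populations at time ``t``.

    Integer-valued in stochastic contexts, real-valued in deterministic
    ones; always nonnegative.
    """

    xU: float
    xI: float
    yU: float
    yI: float
    z: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            if getattr(self, name) < 0:
                raise ValidationError(f"abundance {name} must be nonnegative")

    def to_array(self, dtype=float) -> np.ndarray:
        return np.array([self.xU, self.xI, self.yU, self.yI, self.z], dtype=dtype)

    @classmethod
    def from_array(cls, arr: Sequence[float], t: float = 0.0) -> "SystemState":
        return cls(*map(float, arr), t=t)

    @property
    def prey(self) -> float:
        return self.xU + self.xI

    @property
    def predator(self) -> float:
        return self.yU + self.yI

    @property
    def parasite(self) -> float:
        """Parasite individuals across all life stages (free-living plus
        those carried by infected hosts)."""
        return self.z + self.xI + self.yI


#: Initial abundances used throughout the reference scenarios:
#: 800 uninfected prey, 100 uninfected predators, 1000 free-living parasites.
REFERENCE_INITIAL_STATE = SystemState(xU=800, xI=0, yU=100, yI=0, z=1000)


# kind codes for propensity factors (used verbatim by the SSA kernel)
_UNARY = 0      # coef * s[i]
_PAIR = 1       # coef * s[i] * s[j]
_SAME_PAIR = 2  # coef * s[i] * (s[i] - 1)   (ordered pairs of one type)

_IDX = {name: k for k, name in enumerate(STATE_VARS)}


@dataclass(frozen=True)
class Reaction:
    """One effective state-changing channel of the jump process.

    ``coef`` folds every parameter factor of the channel (rate constant
    times branching probabilities); the propensity is ``coef`` times a
    mass-action factor in the current abundances.  ``delta`` is the
    integer state change over ``(xU, xI, yU, yI, z)``.
    """

    label: str
    coef: float
    kind: int
    i: int
    j: int
    delta: tuple

    def propensity(self, state) -> float:
        s = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
        if self.kind == _UNARY:
            return self.coef * s[self.i]
        if self.kind == _PAIR:
            return self.coef * s[self.i] * s[self.j]
        return self.coef * s[self.i] * max(s[self.i] - 1.0, 0.0)

    # alias matching the "rate law" vocabulary
    def rate_law(self, state, params=None) -> float:
        return self.propensity(state)


def _delta(**changes) -> tuple:
    d = [0] * 5
    for name, v in changes.items():
        d[_IDX[name]] = v
    return tuple(d)


def build_reaction_network(p: Params) -> list:
    """All effective state-changing channels implied by the model.

    Branching outcomes of one encounter type (infect or not, produce an
    offspring or not) are represented as separate exclusive channels with
    the branching probabilities folded into the rate coefficients, which
    is distributionally identical to a two-stage draw.  Encounters whose
    product equals their reactants (e.g. a failed prey infection) carry no
    state change and are omitted.  Same-type competition uses ordered-pair
    counts ``n(n-1)/K`` so a lone individual never competes with itself;
    cross-type competition acts at ``n m / K`` in each direction.
    """
    gx, rx, dx, K = p.gx, p.rx, p.dx, p.K
    S, Qx, nz, dz = p.S, p.Qx, p.nz, p.dz
    fy, ky, Qy, rp, re_, dy = p.fy, p.ky, p.Qy, p.rp, p.re, p.dy

    R = Reaction
    xU, xI, yU, yI, z = (_IDX[n] for n in STATE_VARS)
    channels = [
        # --- prey reproduction (infected prey offspring are uninfected) ---
        R("prey birth (from uninfected)", gx, _UNARY, xU, -1, _delta(xU=+1)),
        R("prey birth (from infected, uninfected offspring)",
          gx * rx, _UNARY, xI, -1, _delta(xU=+1)),
        # --- intra-specific prey competition, rate 1/K per ordered pair ---
        R("competition xU-xU", 1.0 / K, _SAME_PAIR, xU, -1, _delta(xU=-1)),
        R("competition xI-xI", 1.0 / K, _SAME_PAIR, xI, -1, _delta(xI=-1)),
        R("competition xI kills xU", 1.0 / K, _PAIR, xI, xU, _delta(xU=-1)),
        R("competition xU kills xI", 1.0 / K, _PAIR, xU, xI, _delta(xI=-1)),
        # --- prey infection by a free-living parasite ---
        R("prey infection", Qx * S, _PAIR, xU, z, _delta(xU=-1, xI=+1, z=-1)),
        # --- predation: uninfected prey, uninfected predator ---
        R("predation xU-yU with offspring",
          ky * fy, _PAIR, xU, yU, _delta(xU=-1, yU=+1)),
        R("predation xU-yU no offspring",
          (1 - ky) * fy, _PAIR, xU, yU, _delta(xU=-1)),
        # --- predation: infected prey, uninfected predator ---
        R("predator infection with offspring",
          rp * ky * Qy * fy, _PAIR, xI, yU,
          _delta(xI=-1, yI=+1, z=+nz)),  # yU -1 (converted) +1 (offspring)
        R("predator infection no offspring",
          (1 - rp * ky) * Qy * fy, _PAIR, xI, yU,
          _delta(xI=-1, yU=-1, yI=+1, z=+nz)),
        R("exposed predation xI-yU with offspring",
          re_ * ky * (1 - Qy) * fy, _PAIR, xI, yU, _delta(xI=-1, yU=+1)),
        R("exposed predation xI-yU no offspring",
          (1 - re_ * ky) * (1 - Qy) * fy, _PAIR, xI, yU, _delta(xI=-1)),
        # --- predation: uninfected prey, infected predator ---
        R("predation xU-yI with offspring",
          rp * ky * fy, _PAIR, xU, yI, _delta(xU=-1, yU=+1)),
        R("predation xU-yI no offspring",
          (1 - rp * ky) * fy, _PAIR, xU, yI, _delta(xU=-1)),
        # --- predation: infected prey, infected predator ---
        R("predator re-infection with offspring",
          rp * rp * ky * Qy * fy, _PAIR, xI, yI, _delta(xI=-1, yU=+1, z=+nz)),
        R("predator re-infection no offspring",
          (1 - rp * rp * ky) * Qy * fy, _PAIR, xI, yI, _delta(xI=-1, z=+nz)),
        R("exposed predation xI-yI with offspring",
          rp * re_ * ky * (1 - Qy) * fy, _PAIR, xI, yI, _delta(xI=-1, yU=+1)),
        R("exposed predation xI-yI no offspring",
          (1 - rp * re_ * ky) * (1 - Qy) * fy, _PAIR, xI, yI, _delta(xI=-1)),
        # --- intrinsic deaths ---
        R("death xU", dx, _UNARY, xU, -1, _delta(xU=-1)),
        R("death xI", dx, _UNARY, xI, -1, _delta(xI=-1)),
        R("death yU", dy, _UNARY, yU, -1, _delta(yU=-1)),
        R("death yI", dy, _UNARY, yI, -1, _delta(yI=-1)),
        R("death z", dz, _UNARY, z, -1, _delta(z=-1)),
    ]
    return channels


def propensities(network: Iterable[Reaction], state) -> np.ndarray:
    """Propensity of every channel at ``state`` (same order as ``network``)."""
    return np.array([r.propensity(state) for r in network])


def mean_field_drift(network: Iterable[Reaction], state) -> np.ndarray:
    """Expected instantaneous drift sum(delta * propensity) over channels.

    On integer states this equals the deterministic right-hand side up to
    the O(1/K) ordered-pair correction of same-type competition:
    ``drift = rhs - (xU/K, xI/K, 0, 0, 0)`` componentwise... more precisely
    ``rhs_xU - drift_xU = -xU/K`` and ``rhs_xI - drift_xI = -xI/K``.
    """
    drift = np.zeros(5)
    for r in network:
        drift += np.asarray(r.delta, float) * r.propensity(state)
    return drift


def network_arrays(network: Sequence[Reaction]):
    """Flatten a channel list into the arrays consumed by the SSA kernel."""
    coef = np.array([r.coef for r in network], float)
    kind = np.array([r.kind for r in network], np.int64)
    ii = np.array([r.i for r in network], np.int64)
    jj = np.array([max(r.j, 0) for r in network], np.int64)
    deltas = np.array([r.delta for r in network], np.int64)
    return coef, kind, ii, jj, deltas


@dataclass
class Trajectory:
    """A time-ordered sequence of system states with provenance metadata.

    ``states`` is an ``(n, 5)`` array over ``(xU, xI, yU, yI, z)``;
    stochastic trajectories hold integer counts, deterministic ones real
    abundances.  ``terminated`` records whether the run reached its
    horizon or was absorbed (all propensities zero).
    """

    times: np.ndarray
    states: np.ndarray
    engine: str                     # "stochastic" | "deterministic"
    params: Params
    seed: int | None = None
    terminated: str = "t_max_reached"   # | "all_absorbed"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 5):
            raise ValidationError("times and states have inconsistent shapes")
        if self.times.size == 0:
            raise ValidationError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1], t=float(self.times[-1]))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.times)
        return df
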