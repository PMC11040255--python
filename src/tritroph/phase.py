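"""Outcome classification, parameter-plane sweeps and threshold location.

A run is summarised by two categorical labels.  *Coexistence* says which
species persist over the long term: the prey alone, prey and predator,
or all three.  *Composition* (defined only under three-species
coexistence) compares infected against uninfected subpopulations within
each host, giving four states: both hosts dominated by infected
individuals, both by uninfected, infected predators with uninfected
prey, or infected prey with uninfected predators.

Deterministic runs are classified on tail-window time averages with a
sub-individual extinction cutoff (default: mean total abundance below
one individual), since the rate equations never reach exact zero.
Stochastic runs use the exact absorbing zeros of the jump process for
extinction and tail averages for composition.  The parasite is counted
across all its life stages (free-living plus inside infected hosts), so
the stochastic rule coincides with the absorbing set xI = yI = z = 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .deterministic import integrate, long_run_summary
from .model import PARAM_NAMES, Params, SystemState, Trajectory, REFERENCE_INITIAL_STATE
from .stochastic import gillespie_run, run_ensemble

__all__ = [
    "Coexistence",
    "Composition",
    "OutcomeLabel",
    "SweepResult",
    "classify",
    "run_and_classify",
    "sweep_plane",
    "find_threshold",
    "aggregate_ensemble",
]


class Coexistence(str, Enum):
    PREY_ONLY = "prey_only"
    PREY_PREDATOR = "prey_predator"
    ALL_THREE = "all_three"


class Composition(str, Enum):
    BOTH_INFECTED = "both_infected_dominant"
    BOTH_UNINFECTED = "both_uninfected_dominant"
    PRED_I_PREY_U = "predI_preyU_dominant"
    PRED_U_PREY_I = "predU_preyI_dominant"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class OutcomeLabel:
    """Categorical summary of one run."""

    coexistence: Coexistence
    composition: Composition

    def __post_init__(self) -> None:
        if (self.composition is not Composition.NOT_APPLICABLE
                and self.coexistence is not Coexistence.ALL_THREE):
            raise ValueError("composition applies only under three-species coexistence")

    def __str__(self) -> str:  # compact, for CSV cells
        return f"{self.coexistence.value}|{self.composition.value}"

    @classmethod
    def parse(cls, text: str) -> "OutcomeLabel":
        co, comp = text.split("|")
        return cls(Coexistence(co), Composition(comp))


def classify(
    traj: Trajectory,
    extinction_threshold: float = 1.0,
    tail_fraction: float = 0.2,
) -> OutcomeLabel:
    """Label one trajectory.

    Deterministic engine: a species is extinct when its tail-mean total
    abundance falls below ``extinction_threshold``.  Stochastic engine:
    extinction is an exact zero of the corresponding total at the final
    state (absorbing in the jump process).  Composition compares
    tail-mean infected vs uninfected abundances within each host; exact
    ties (a measure-zero event) count as uninfected-dominant.
    """
    summ = long_run_summary(traj, tail_fraction)
    m = summ.mean
    if traj.engine == "stochastic":
        fin = traj.final_state
        predator_extinct = fin.predator == 0
        parasite_extinct = fin.parasite == 0
    else:
        predator_extinct = (m["yU"] + m["yI"]) < extinction_threshold
        parasite_extinct = (m["z"] + m["xI"] + m["yI"]) < extinction_threshold
    if predator_extinct:
        return OutcomeLabel(Coexistence.PREY_ONLY, Composition.NOT_APPLICABLE)
    if parasite_extinct:
        return OutcomeLabel(Coexistence.PREY_PREDATOR, Composition.NOT_APPLICABLE)
    prey_infected = m["xI"] > m["xU"]
    pred_infected = m["yI"] > m["yU"]
    if prey_infected and pred_infected:
        comp = Composition.BOTH_INFECTED
    elif prey_infected:
        comp = Composition.PRED_U_PREY_I
    elif pred_infected:
        comp = Composition.PRED_I_PREY_U
    else:
        comp = Composition.BOTH_UNINFECTED
    return OutcomeLabel(Coexistence.ALL_THREE, comp)


def run_and_classify(
    p: Params,
    engine: str = "deterministic",
    state0: SystemState = REFERENCE_INITIAL_STATE,
    t_max: float | None = None,
    seed: int | None = None,
    extinction_threshold: float = 1.0,
    tail_fraction: float = 0.2,
    sample_dt: float = 0.1,
) -> OutcomeLabel:
    """Integrate or simulate from ``state0`` and classify the outcome."""
    if engine == "deterministic":
        traj = integrate(state0, p, t_max=2000.0 if t_max is None else t_max,
                         sample_dt=sample_dt)
    elif engine == "stochastic":
        if seed is None:
            raise ValueError("stochastic engine requires a seed")
        traj = gillespie_run(state0, p, t_max=1000.0 if t_max is None else t_max,
                             seed=seed, sample_dt=sample_dt)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return classify(traj, extinction_threshold, tail_fraction)


def aggregate_ensemble(labels: list) -> dict:
    """Relative frequency of each outcome label; frequencies sum to 1."""
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(str(lab) for lab in labels)
    n = len(labels)
    return {OutcomeLabel.parse(k): v / n for k, v in sorted(counts.items())}


@dataclass
class SweepResult:
    """Classified outcomes over a 2-D parameter plane.

    ``labels[i, j]`` (deterministic) or ``frequencies[i, j]`` (stochastic,
    a label -> frequency dict) corresponds to ``grid1[i]``, ``grid2[j]``.
    """

    axis1: str
    axis2: str
    grid1: np.ndarray
    grid2: np.ndarray
    engine: str
    labels: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self):
        """Long-format table: axis1, axis2, coexistence, composition, frequency."""
        import pandas as pd

        rows = []
        for i, v1 in enumerate(self.grid1):
            for j, v2 in enumerate(self.grid2):
                if self.engine == "deterministic":
                    cell = {str(self.labels[i, j]): 1.0}
                else:
                    cell = {str(k): v for k, v in self.frequencies[i, j].items()}
                for text, freq in cell.items():
                    lab = OutcomeLabel.parse(text)
                    rows.append({
                        self.axis1: v1, self.axis2: v2,
                        "coexistence": lab.coexistence.value,
                        "composition": lab.composition.value,
                        "frequency": freq,
                    })
        return pd.DataFrame(rows)

    def write(self, csv_path, json_path=None) -> None:
        import json
        from pathlib import Path

        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path, index=False)
        meta = dict(self.metadata, axis1=self.axis1, axis2=self.axis2,
                    engine=self.engine,
                    grid1=list(map(float, self.grid1)),
                    grid2=list(map(float, self.grid2)))
        with open(json_path or csv_path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    def plot(self, path) -> None:
        """Heat map with the conventional colour semantics: magenta =
        three species / both-uninfected, yellow = prey+predator /
        infected-predator, cyan = prey-only / both-infected, black =
        infected-prey with uninfected-predator; stochastic cells blend
        colours by outcome frequencies."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rgb = np.zeros((self.grid1.size, self.grid2.size, 3))
        for i in range(self.grid1.size):
            for j in range(self.grid2.size):
                if self.engine == "deterministic":
                    cell = {self.labels[i, j]: 1.0}
                else:
                    cell = self.frequencies[i, j]
                for lab, freq in cell.items():
                    rgb[i, j] += freq * np.array(_label_rgb(lab))
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.imshow(np.transpose(rgb, (1, 0, 2)), origin="lower", aspect="auto",
                  extent=(self.grid1[0], self.grid1[-1],
                          self.grid2[0], self.grid2[-1]))
        ax.set_xlabel(self.axis1)
        ax.set_ylabel(self.axis2)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


_COEX_RGB = {
    Coexistence.PREY_ONLY: (0.0, 1.0, 1.0),      # cyan
    Coexistence.PREY_PREDATOR: (1.0, 1.0, 0.0),  # yellow
    Coexistence.ALL_THREE: (1.0, 0.0, 1.0),      # magenta
}
_COMP_RGB = {
    Composition.BOTH_INFECTED: (0.0, 1.0, 1.0),    # cyan
    Composition.BOTH_UNINFECTED: (1.0, 0.0, 1.0),  # magenta
    Composition.PRED_I_PREY_U: (1.0, 1.0, 0.0),    # yellow
    Composition.PRED_U_PREY_I: (0.0, 0.0, 0.0),    # black
}


def _label_rgb(label: OutcomeLabel):
    if label.coexistence is Coexistence.ALL_THREE:
        return _COMP_RGB[label.composition]
    return _COEX_RGB[label.coexistence]


def sweep_plane(
    base: Params,
    axis1: str,
    grid1,
    axis2: str,
    grid2,
    engine: str = "deterministic",
    n_reps: int = 100,
    base_seed: int = 0,
    state0: SystemState = REFERENCE_INITIAL_STATE,
    t_max: float | None = None,
    extinction_threshold: float = 1.0,
    tail_fraction: float = 0.2,
    sample_dt: float = 0.1,
) -> SweepResult:
    """Classify every cell of a 2-D parameter grid.

    Stochastic cells run ``n_reps`` replicates; replicate ``r`` of cell
    number ``c`` (row-major) uses seed ``base_seed + c * n_reps + r``, so
    cells are independent and reproducible in any execution order.
    """
    for ax in (axis1, axis2):
        if ax not in PARAM_NAMES:
            raise ValueError(f"invalid axis name {ax!r}")
    grid1 = np.asarray(grid1, float)
    grid2 = np.asarray(grid2, float)
    if t_max is None:
        t_max = 2000.0 if engine == "deterministic" else 1000.0
    labels = np.empty((grid1.size, grid2.size), dtype=object)
    freqs = np.empty((grid1.size, grid2.size), dtype=object)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            p = base.replace(**{axis1: float(v1), axis2: float(v2)})
            if engine == "deterministic":
                labels[i, j] = classify(
                    integrate(state0, p, t_max=t_max, sample_dt=sample_dt),
                    extinction_threshold, tail_fraction)
            else:
                cell = i * grid2.size + j
                reps = run_ensemble(state0, p, t_max, n_reps,
                                    base_seed=base_seed + cell * n_reps,
                                    sample_dt=sample_dt)
                freqs[i, j] = aggregate_ensemble(
                    [classify(tr, extinction_threshold, tail_fraction)
                     for tr in reps])
    meta = dict(base_params=base.to_dict(), t_max=t_max, n_reps=n_reps,
                base_seed=base_seed,
                extinction_threshold=extinction_threshold,
                tail_fraction=tail_fraction)
    if engine == "deterministic":
        return SweepResult(axis1, axis2, grid1, grid2, engine,
                           labels=labels, metadata=meta)
    return SweepResult(axis1, axis2, grid1, grid2, engine,
                       frequencies=freqs, metadata=meta)


def find_threshold(
    base: Params,
    axis: str,
    predicate,
    bracket: tuple,
    tol: float = 0.005,
    evaluate=None,
    **run_kwargs,
) -> float:
    """Bisection for the parameter value where ``predicate`` flips.

    ``predicate`` maps an :class:`OutcomeLabel` to bool (or is a
    :class:`Coexistence`/:class:`Composition` member, matched against
    the label).  ``evaluate`` defaults to a deterministic
    run-and-classify; it can be overridden (e.g. in tests).  Raises
    ``ValueError`` when the predicate agrees at both bracket endpoints.
    """
    if axis not in PARAM_NAMES:
        raise ValueError(f"invalid axis name {axis!r}")
    pred = _as_predicate(predicate)
    if evaluate is None:
        def evaluate(value: float) -> OutcomeLabel:
            return run_and_classify(base.replace(**{axis: float(value)}),
                                    engine="deterministic", **run_kwargs)
    lo, hi = float(bracket[0]), float(bracket[1])
    p_lo, p_hi = pred(evaluate(lo)), pred(evaluate(hi))
    if p_lo == p_hi:
        raise ValueError(
            f"predicate is {p_lo} at both ends of bracket {bracket}: no crossing")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pred(evaluate(mid)) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _as_predicate(predicate):
    if isinstance(predicate, Coexistence):
        return lambda lab: lab.coexistence is predicate
    if isinstance(predicate, Composition):
        return lambda lab: lab.composition is predicate
    if callable(predicate):
        return predicate
    raise TypeError(f"cannot interpret predicate {predicate!r}")
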