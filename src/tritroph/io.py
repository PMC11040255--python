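"""Trajectory persistence: tidy CSV plus a JSON metadata sidecar.

The CSV holds columns ``t, xU, xI, yU, yI, z``; the sidecar records the
parameter set, engine, seed and termination reason.  Integer (stochastic)
states round-trip bit-exactly; deterministic states are written with
full ``repr`` precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import STATE_VARS, Trajectory, make_params

__all__ = ["write_trajectory", "read_trajectory"]


def _sidecar(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trajectory(traj: Trajectory, csv_path) -> Path:
    csv_path = Path(csv_path)
    df = traj.to_dataframe()
    if traj.engine == "stochastic":
        df[list(STATE_VARS)] = df[list(STATE_VARS)].astype(np.int64)
    df.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "engine": traj.engine,
        "seed": traj.seed,
        "terminated": traj.terminated,
        "params": traj.params.to_dict(),
    }
    with open(_sidecar(csv_path), "w") as fh:
        json.dump(meta, fh, indent=2)
    return csv_path


def read_trajectory(csv_path) -> Trajectory:
    csv_path = Path(csv_path)
    with open(_sidecar(csv_path)) as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    states = df[list(STATE_VARS)].to_numpy()
    if meta["engine"] == "stochastic":
        states = states.astype(np.int64)
    return Trajectory(
        times=df["t"].to_numpy(float),
        states=states,
        engine=meta["engine"],
        params=make_params(meta["params"]),
        seed=meta["seed"],
        terminated=meta["terminated"],
    )
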