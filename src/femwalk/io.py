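"""Plain-text trial I/O.

Trials are stored as delimited text (TSV by default): one row per 2 ms
sample with columns ``trial, time, x_hor, x_ver`` and, for binocular
data, ``x_hor_right, x_ver_right``.  Metadata (dt, unit label, set
label) travels in ``#``-prefixed header comments.  The format
round-trips at double precision; binary eye-tracker formats are out of
scope.

A path may also be a directory, in which case every ``*.tsv`` file in it
(sorted) contributes its trials.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Trajectory, TrialSet

__all__ = ["read_trials", "write_trials"]

#: column names used on write and expected (by default) on read
DEFAULT_LAYOUT = {
    "trial": "trial",
    "time": "time",
    "x": "x_hor",
    "y": "x_ver",
    "x_right": "x_hor_right",
    "y_right": "x_ver_right",
}

_REL_TOL_DT = 1e-9


def write_trials(trials: TrialSet, path: str | os.PathLike, sep: str = "\t") -> None:
    """Write a TrialSet to one delimited text file.

    Floats are written with 17 significant digits so that
    ``read_trials(write_trials(ts))`` reproduces the positions exactly.
    An empty TrialSet yields a header-only file.
    """
    path = Path(path)
    cols = ["trial", "time", "x_hor", "x_ver"]
    binoc = trials.binocular
    if binoc:
        cols += ["x_hor_right", "x_ver_right"]

    dt = trials.trials[0].dt if trials.trials else float("nan")
    unit = trials.trials[0].unit_label if trials.trials else "deg"
    with open(path, "w") as fh:
        fh.write(f"# dt = {dt!r}\n")
        fh.write(f"# unit = {unit}\n")
        fh.write(f"# label = {trials.label}\n")
        fh.write(sep.join(cols) + "\n")
        for idx, traj in enumerate(trials.trials):
            pos = traj.positions
            if pos.shape[1] == 1:  # store 1-D trials with a zero vertical column
                pos = np.column_stack([pos[:, 0], np.zeros(len(pos))])
            block = [np.full(len(pos), idx), np.arange(len(pos)) * traj.dt, pos[:, 0], pos[:, 1]]
            if binoc:
                rpos = trials.right[idx].positions
                block += [rpos[:, 0], rpos[:, 1]]
            arr = np.column_stack(block)
            np.savetxt(fh, arr, fmt=["%d"] + ["%.17g"] * (len(cols) - 1), delimiter=sep)


def read_trials(path: str | os.PathLike, layout: dict | None = None) -> TrialSet:
    """Read a TrialSet from a delimited file or a directory of them.

    The sample interval is inferred from the time column and must be
    uniform to a relative tolerance of 1e-9; rows with missing values
    cause rejection of the whole file, mirroring the aborted-trial
    policy of the recordings this format emulates.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tsv")) + sorted(path.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no *.tsv/*.csv files in {path}")
        parts = [read_trials(f, layout) for f in files]
        trials: list[Trajectory] = []
        right: list[Trajectory] | None = [] if parts[0].binocular else None
        for p in parts:
            trials.extend(p.trials)
            if right is not None:
                if not p.binocular:
                    raise ValueError("mixed monocular/binocular files in directory")
                right.extend(p.right)
        return TrialSet(trials, right=right, label=parts[0].label)

    lay = dict(DEFAULT_LAYOUT)
    if layout:
        lay.update(layout)

    unit = "deg"
    label = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition("=")
            key, val = key.strip(), val.strip()
            if key == "unit":
                unit = val
            elif key == "label":
                label = val

    sep = None  # sniff whitespace vs comma
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                sep = "," if "," in line else "\t"
                break
    if sep is None:
        return TrialSet([], label=label)

    df = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    if df.empty:
        return TrialSet([], label=label)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values — file rejected")

    tcol, xcol, ycol = lay["time"], lay["x"], lay["y"]
    for c in (tcol, xcol):
        if c not in df.columns:
            raise ValueError(f"{path}: required column {c!r} not found")
    has_y = ycol in df.columns
    binoc = lay["x_right"] in df.columns

    if lay["trial"] in df.columns:
        groups = [g for _, g in df.groupby(lay["trial"], sort=True)]
    else:
        groups = [df]

    trials, right = [], ([] if binoc else None)
    for g in groups:
        t = g[tcol].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"{path}: trial too short to infer dt")
        steps = np.diff(t)
        dt = steps.mean()
        if dt <= 0 or np.abs(steps - dt).max() > _REL_TOL_DT * abs(dt):
            raise ValueError(f"{path}: non-uniform time step — file rejected")
        if has_y:
            pos = g[[xcol, ycol]].to_numpy(float)
        else:
            pos = g[[xcol]].to_numpy(float)
        trials.append(Trajectory(pos, dt=dt, unit_label=unit))
        if binoc:
            rpos = g[[lay["x_right"], lay["y_right"]]].to_numpy(float)
            right.append(Trajectory(rpos, dt=dt, unit_label=unit))
    return TrialSet(trials, right=right, label=label)
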