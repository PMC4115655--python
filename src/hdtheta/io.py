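"""Delimited-text session formats.

A session directory holds three plain-text files:

- ``tracking.csv`` — header ``t,x1,y1,x2,y2``; seconds and centimetres,
  '.' decimal, comma separator; (x1, y1) is the front LED, (x2, y2) the back.
- ``spikes.csv`` — header ``unit_id,t``; one row per spike, sorted in time
  within each unit.
- ``session.cfg`` — ``key = value`` sidecar recording the arena, seed and
  (for synthetic sessions) the generative ground truth of each unit.

Readers validate the dialect and report the offending line number; writing
then reading reproduces the arrays to float round-trip precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .session import ArenaSpec, GroundTruth, SpikeTrain, Trajectory

TRACKING_NAME = "tracking.csv"
SPIKES_NAME = "spikes.csv"
CONFIG_NAME = "session.cfg"
_TRACK_COLS = ["t", "x1", "y1", "x2", "y2"]
_FLOAT_FMT = "%.9g"


def write_tracking(path, traj: Trajectory) -> None:
    arr = np.column_stack([traj.timestamps, traj.led_front, traj.led_back])
    header = ",".join(_TRACK_COLS)
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt=_FLOAT_FMT)


def write_spikes(path, trains: Sequence[SpikeTrain]) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id,t\n")
        for tr in trains:
            for t in tr.spike_times:
                fh.write(f"{tr.unit_id},{t:.9g}\n")


def write_config(path, arena: ArenaSpec, sample_rate: float, duration_s: float,
                 seed: Optional[int] = None,
                 truths: Optional[Dict[str, GroundTruth]] = None) -> None:
    lines = [f"arena.shape = {arena.shape}",
             f"arena.diameter_cm = {arena.diameter_cm}",
             f"arena.side_cm = {arena.side_cm}",
             f"sample_rate = {sample_rate}",
             f"duration_s = {duration_s}"]
    if seed is not None:
        lines.append(f"seed = {seed}")
    for uid, truth in (truths or {}).items():
        for key, val in truth.to_dict().items():
            lines.append(f"truth.{uid}.{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_session(directory, traj: Trajectory, trains: Sequence[SpikeTrain],
                  truths: Optional[Dict[str, GroundTruth]] = None,
                  seed: Optional[int] = None) -> Path:
    """Write tracking, spikes and config sidecar into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tracking(directory / TRACKING_NAME, traj)
    write_spikes(directory / SPIKES_NAME, trains)
    write_config(directory / CONFIG_NAME, traj.arena, traj.sample_rate,
                 traj.duration_s, seed=seed, truths=truths)
    return directory


def read_config(path) -> Dict[str, str]:
    out = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(path, i, f"expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def _arena_from_config(cfg: Dict[str, str]) -> ArenaSpec:
    return ArenaSpec(shape=cfg.get("arena.shape", "circle"),
                     diameter_cm=float(cfg.get("arena.diameter_cm", 96.0)),
                     side_cm=float(cfg.get("arena.side_cm", 60.0)))


def read_tracking(path, arena: ArenaSpec,
                  sample_rate: Optional[float] = None) -> Trajectory:
    """Read a tracking file; validates columns and timestamp monotonicity.

    ``sample_rate`` defaults to the reciprocal median timestamp step.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(path, None, f"unreadable tracking file: {exc}") from exc
    missing = [c for c in _TRACK_COLS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns: {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if t.size == 0:
        raise ParseError(path, 2, "tracking file has no samples")
    values = df[_TRACK_COLS].to_numpy(dtype=float)
    row_bad = ~np.isfinite(values).all(axis=1)
    if row_bad.any():
        raise ParseError(path, int(np.where(row_bad)[0][0]) + 2,
                         "non-finite value in tracking row")
    if t[0] < 0:
        raise ParseError(path, 2, "negative timestamp")
    steps = np.diff(t)
    if np.any(steps <= 0):
        bad = int(np.where(steps <= 0)[0][0])
        raise ParseError(path, bad + 3, "timestamps not strictly increasing")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(steps)) if steps.size else 50.0
    return Trajectory(timestamps=t,
                      led_front=df[["x1", "y1"]].to_numpy(dtype=float),
                      led_back=df[["x2", "y2"]].to_numpy(dtype=float),
                      arena=arena, sample_rate=sample_rate)


def read_spikes(path, session_duration: float) -> List[SpikeTrain]:
    """Read a spikes file into one SpikeTrain per unit.

    Spikes beyond the tracking extent are dropped with a warning (documented
    truncation policy); negative or non-monotone times within a unit are
    rejected with the offending line number.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(path, None, f"unreadable spikes file: {exc}") from exc
    for col in ("unit_id", "t"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column: {col}")
    times = df["t"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        bad = int(np.where(~np.isfinite(times))[0][0])
        raise ParseError(path, bad + 2, "non-finite spike time")
    if np.any(times < 0):
        bad = int(np.where(times < 0)[0][0])
        raise ParseError(path, bad + 2, "negative spike time")
    trains = []
    for uid, grp in df.groupby("unit_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            bad = int(grp.index[int(np.where(np.diff(t) < 0)[0][0]) + 1])
            raise ParseError(path, bad + 2,
                             f"spike times of unit {uid!r} not sorted ascending")
        beyond = t > session_duration + 1e-9
        if beyond.any():
            warnings.warn(f"unit {uid!r}: {int(beyond.sum())} spikes beyond the "
                          f"tracking extent ({session_duration:g} s) were dropped")
            t = t[~beyond]
        trains.append(SpikeTrain(unit_id=str(uid), spike_times=t,
                                 session_duration=session_duration))
    return trains


def read_session(directory):
    """Read a full session directory -> (Trajectory, [SpikeTrain], config dict)."""
    directory = Path(directory)
    cfg = read_config(directory / CONFIG_NAME)
    arena = _arena_from_config(cfg)
    rate = float(cfg["sample_rate"]) if "sample_rate" in cfg else None
    traj = read_tracking(directory / TRACKING_NAME, arena, sample_rate=rate)
    trains = read_spikes(directory / SPIKES_NAME, traj.duration_s)
    return traj, trains, cfg


def write_report(df: pd.DataFrame, path) -> None:
    """Write an analysis report as a tab-separated table."""
    df.to_csv(path, sep="\t", index=False)


def write_matrix(path, matrix: np.ndarray, bin_cm: float, origin_cm: float,
                 arena: ArenaSpec) -> None:
    """Write a 2-D map as a delimited-text matrix with a small header."""
    with open(path, "w") as fh:
        fh.write(f"# bin_cm = {bin_cm}\n# origin_cm = {origin_cm}\n"
                 f"# arena = {arena.shape}\n")
        np.savetxt(fh, np.nan_to_num(matrix, nan=-1.0), delimiter=",", fmt=_FLOAT_FMT)
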