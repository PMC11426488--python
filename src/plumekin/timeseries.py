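"""In-memory containers and CSV readers/writers for the per-trial data streams.

All time series are uniformly sampled and addressed by time in seconds;
streams with different rates are aligned by nearest-sample lookup, never by
resampling.  Keypoint files use the pose-estimator CSV dialect with the
three-row (scorer / bodyparts / coords) header.  Image coordinates are
origin top-left with y increasing downward; angle code converts to a y-up
mathematical frame internally (see :mod:`plumekin.kinematics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "KeypointTrack",
    "TrialRecord",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_keypoint_csv",
    "write_keypoint_csv",
]

BODYPARTS = ("nose", "neck", "body")


@dataclass
class TimeSeries:
    """A uniformly sampled series: one channel ``(n,)`` or several ``(n, c)``."""

    t0: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D or 2-D (samples x channels)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t) -> np.ndarray:
        """Nearest sample index for time(s) ``t`` (clipped to the series)."""
        idx = np.rint((np.asarray(t) - self.t0) * self.fs).astype(int)
        return np.clip(idx, 0, self.n - 1)

    def channel(self, i: int) -> "TimeSeries":
        if self.values.ndim == 1:
            if i != 0:
                raise IndexError("single-channel series")
            return self
        return TimeSeries(self.t0, self.fs, self.values[:, i])

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.t0, self.fs, np.asarray(values, dtype=float))


@dataclass
class KeypointTrack:
    """Per-frame nose/neck/body pixel coordinates with pose-estimator likelihoods.

    Coordinates are image-style (origin top-left, y down).  Masked keypoints
    are NaN.
    """

    fps: float
    nose: np.ndarray  # (n, 2) px
    neck: np.ndarray
    body: np.ndarray
    nose_p: np.ndarray  # (n,) likelihood in [0, 1]
    neck_p: np.ndarray
    body_p: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nose", "neck", "body"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must have shape (n, 2)")
            setattr(self, name, arr)
        n = self.nose.shape[0]
        for name in ("nose_p", "neck_p", "body_p"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
                raise ValueError(f"{name} likelihoods must lie in [0, 1]")
            setattr(self, name, p)
        if self.neck.shape[0] != n or self.body.shape[0] != n:
            raise ValueError("keypoint arrays must share length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n(self) -> int:
        return self.nose.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fps

    def index_at(self, t) -> np.ndarray:
        idx = np.rint((np.asarray(t) - self.t0) * self.fps).astype(int)
        return np.clip(idx, 0, self.n - 1)

    def copy(self) -> "KeypointTrack":
        return KeypointTrack(
            self.fps,
            self.nose.copy(), self.neck.copy(), self.body.copy(),
            self.nose_p.copy(), self.neck_p.copy(), self.body_p.copy(),
            self.t0,
        )


@dataclass
class TrialRecord:
    """One trial's synchronized streams plus arena metadata (pixels, seconds)."""

    trial_id: str
    sensor: TimeSeries
    accel: TimeSeries
    keypoints: KeypointTrack
    port_xy: tuple[float, float]
    arena_bounds: tuple[float, float, float, float]  # x0, y0, x1, y1
    in_arena: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accel.n_channels != 3:
            raise ValueError("accel must have 3 channels")
        x0, y0, x1, y1 = self.arena_bounds
        px, py = self.port_xy
        if not (x0 <= px <= x1 and y0 <= py <= y1):
            raise ValueError("port_xy must lie inside arena_bounds")
        if not self.in_arena:
            self.in_arena = [(self.sensor.t0, self.sensor.t0 + self.sensor.duration)]
        for a, b in self.in_arena:
            if b <= a:
                raise ValueError("in_arena intervals must have positive length")


def _uniform_fs(t: np.ndarray, jitter: float = 1e-6) -> tuple[float, float]:
    """Validate a monotone uniform time column; return (t0, fs)."""
    if len(t) < 2:
        raise ValueError("time column needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column t must be strictly increasing")
    if np.max(np.abs(dt - dt.mean())) > jitter:
        raise ValueError("time column t is not uniformly sampled (jitter > 1e-6 s)")
    return float(t[0]), float(1.0 / dt.mean())


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    """Read a ``t,value`` or ``t,x,y,z`` CSV into a :class:`TimeSeries`."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError(f"{path}: missing required column 't'")
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        bad = [c for c, d in zip(df.columns, df.dtypes) if not np.issubdtype(d, np.number)]
        raise ValueError(f"{path}: non-numeric column(s) {bad}")
    t0, fs = _uniform_fs(df["t"].to_numpy(dtype=float))
    vals = df.drop(columns="t").to_numpy(dtype=float)
    if vals.shape[1] == 0:
        raise ValueError(f"{path}: no value columns")
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    return TimeSeries(t0, fs, vals)


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> None:
    vals = ts.values if ts.values.ndim == 2 else ts.values[:, None]
    if vals.shape[1] == 1:
        cols = ["value"]
    elif vals.shape[1] == 3:
        cols = ["x", "y", "z"]
    else:
        cols = [f"ch{i}" for i in range(vals.shape[1])]
    df = pd.DataFrame(vals, columns=cols)
    df.insert(0, "t", ts.times)
    df.to_csv(path, index=False, float_format="%.9g")


def read_keypoint_csv(path: str | Path, fps: float) -> KeypointTrack:
    """Read a pose-estimator CSV (3-row scorer/bodyparts/coords header)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    cols = {}
    for part in BODYPARTS:
        for coord in ("x", "y", "likelihood"):
            match = [
                c for c in df.columns
                if c[1].strip().lower() == part and c[2].strip().lower() == coord
            ]
            if not match:
                raise ValueError(f"{path}: missing column for bodypart '{part}' coord '{coord}'")
            col = df[match[0]]
            if not np.issubdtype(col.dtype, np.number):
                raise ValueError(f"{path}: non-numeric data in column {part}/{coord}")
            cols[(part, coord)] = col.to_numpy(dtype=float)
    return KeypointTrack(
        fps=fps,
        nose=np.column_stack([cols[("nose", "x")], cols[("nose", "y")]]),
        neck=np.column_stack([cols[("neck", "x")], cols[("neck", "y")]]),
        body=np.column_stack([cols[("body", "x")], cols[("body", "y")]]),
        nose_p=cols[("nose", "likelihood")],
        neck_p=cols[("neck", "likelihood")],
        body_p=cols[("body", "likelihood")],
    )


def write_keypoint_csv(track: KeypointTrack, path: str | Path, scorer: str = "plumekin") -> None:
    data, columns = [], []
    for part in BODYPARTS:
        xy = getattr(track, part)
        p = getattr(track, f"{part}_p")
        for coord, arr in (("x", xy[:, 0]), ("y", xy[:, 1]), ("likelihood", p)):
            columns.append((scorer, part, coord))
            data.append(arr)
    df = pd.DataFrame(
        np.column_stack(data),
        columns=pd.MultiIndex.from_tuples(columns, names=["scorer", "bodyparts", "coords"]),
    )
    df.to_csv(path, index=True, float_format="%.9g")
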