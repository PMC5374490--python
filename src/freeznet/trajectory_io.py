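"""Reading, calibration, cleaning and smoothing of per-frame 3D tracking data.

Upstream video-tracking software (EthoVision and kin) exports one (x, y, z)
fix per video frame for the focal fish.  This module turns such an export
into an analysis-ready :class:`Trajectory`: positions calibrated to
centimetres, a time axis in seconds (``t = frame / frame_rate``), an explicit
validity mask for tracking dropouts, short-gap interpolation, and moving
average smoothing prior to speed computation.

The only accepted interchange format is CSV with a ``frame,x,y,z`` header
(comma separator, dot decimal).  Missing samples are encoded as empty cells
or a sentinel such as ``NA``; they enter the trajectory as ``valid=False``
samples and are excluded from every percent-time denominator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArenaCalibration",
    "Trajectory",
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "interpolate_gaps",
    "smooth_positions",
]

#: Cell contents treated as a missing coordinate (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "none", "null", "-"})


class TrajectoryParseError(ValueError):
    """Raised when a trajectory CSV violates the format contract."""


@dataclass(frozen=True)
class ArenaCalibration:
    """Camera/arena calibration for one recording setup.

    Parameters
    ----------
    frame_rate
        Acquisition rate in frames per second.
    unit_scale
        Centimetres per raw coordinate unit (1.0 when the tracker already
        exports cm).
    arena_bounds
        ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` in cm.  Used for
        validity checks and as reflective walls by the simulator.
    """

    frame_rate: float = 30.0
    unit_scale: float = 1.0
    arena_bounds: tuple[tuple[float, float], ...] = (
        (0.0, 30.0),
        (0.0, 15.0),
        (0.0, 25.0),
    )

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not self.unit_scale > 0:
            raise ValueError(f"unit_scale must be > 0, got {self.unit_scale}")
        if len(self.arena_bounds) != 3:
            raise ValueError("arena_bounds needs one (min, max) pair per axis")
        for lo, hi in self.arena_bounds:
            if not lo < hi:
                raise ValueError(f"arena bound min must be < max, got ({lo}, {hi})")


@dataclass
class Trajectory:
    """Time-ordered 3D position samples for one focal fish.

    ``t`` is seconds from recording start (frame 0), ``pos`` an ``(n, 3)``
    array in cm, ``valid`` marks samples where tracking succeeded.
    ``protocol_onset`` is the time at which the alarm substance (or control
    water) was administered; the standard protocol records a 5-minute
    baseline, so it defaults to 300 s.
    """

    fish_id: str
    treatment: str
    t: np.ndarray
    pos: np.ndarray
    valid: np.ndarray
    frame_rate: float
    protocol_onset: float = 300.0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if self.pos.shape != (n, 3) or len(self.valid) != n:
            raise ValueError("t, pos and valid must have matching lengths")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-6):
                raise ValueError("t spacing must equal 1/frame_rate")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        """Recorded duration in seconds (last frame end)."""
        return float(self.t[-1]) + self.dt if self.n else 0.0

    def copy(self) -> "Trajectory":
        return replace(
            self,
            t=self.t.copy(),
            pos=self.pos.copy(),
            valid=self.valid.copy(),
            warnings=list(self.warnings),
        )


def _parse_cell(token: str, line_no: int, column: str) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise TrajectoryParseError(
            f"line {line_no}: malformed value {token!r} in column {column!r}"
        ) from None


def read_trajectory(
    path,
    calib: ArenaCalibration,
    *,
    fish_id: str | None = None,
    treatment: str = "",
    protocol_onset: float = 300.0,
) -> Trajectory:
    """Read a ``frame,x,y,z`` CSV into a calibrated :class:`Trajectory`.

    Frames must be strictly increasing integers; skipped frame numbers are
    filled in as invalid samples so the time axis stays uniform.  Raw
    coordinates are multiplied by ``calib.unit_scale`` to obtain cm.

    Raises
    ------
    TrajectoryParseError
        On a missing/extra header, a malformed cell (with its line number),
        non-monotone frame numbers, or an empty file.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise TrajectoryParseError(f"{path}: empty file") from None
    required = ["frame", "x", "y", "z"]
    if [c.strip() for c in df.columns[:4]] != required:
        raise TrajectoryParseError(
            f"{path}: header must start with {','.join(required)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise TrajectoryParseError(f"{path}: no data rows")

    frames = np.empty(len(df), dtype=np.int64)
    for i, token in enumerate(df["frame"].to_numpy()):
        line_no = i + 2  # 1-based, after the header line
        value = _parse_cell(str(token), line_no, "frame")
        if not np.isfinite(value) or value != int(value):
            raise TrajectoryParseError(f"line {line_no}: frame must be an integer")
        frames[i] = int(value)
    if np.any(np.diff(frames) <= 0):
        bad = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 3
        raise TrajectoryParseError(f"line {bad}: frame numbers not strictly increasing")

    raw = np.empty((len(df), 3))
    for j, col in enumerate(("x", "y", "z")):
        col_tokens = df[col].to_numpy()
        for i, token in enumerate(col_tokens):
            raw[i, j] = _parse_cell(str(token), i + 2, col)

    # Re-index onto a contiguous frame axis; skipped frames become dropouts.
    first, last = frames[0], frames[-1]
    n = int(last - first + 1)
    pos = np.full((n, 3), np.nan)
    pos[frames - first] = raw * calib.unit_scale
    valid = ~np.any(np.isnan(pos), axis=1)
    pos[~valid] = 0.0

    t = (np.arange(n) + first) / calib.frame_rate
    if fish_id is None:
        fish_id = _stem(path)
    return Trajectory(
        fish_id=fish_id,
        treatment=treatment,
        t=t,
        pos=pos,
        valid=valid,
        frame_rate=calib.frame_rate,
        protocol_onset=protocol_onset,
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write ``frame,x,y,z`` CSV; invalid samples become empty cells.

    Floats use the shortest round-trip representation, so a write/read cycle
    reproduces ``t``, ``pos`` and ``valid`` bit-exactly.
    """
    frames = np.rint(traj.t * traj.frame_rate).astype(np.int64)
    with open(path, "w") as fh:
        fh.write("frame,x,y,z\n")
        for i in range(traj.n):
            if traj.valid[i]:
                x, y, z = (repr(float(v)) for v in traj.pos[i])
                fh.write(f"{frames[i]},{x},{y},{z}\n")
            else:
                fh.write(f"{frames[i]},,,\n")


def interpolate_gaps(traj: Trajectory, max_gap: int) -> Trajectory:
    """Linearly fill dropout runs of length <= ``max_gap`` frames.

    Runs must be flanked by valid samples on both sides; longer runs and
    runs touching the recording edges stay invalid.  Valid samples are
    untouched, so the operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not traj.valid.any():
        raise ValueError("trajectory has no valid samples")
    out = traj.copy()
    if max_gap == 0:
        return out
    valid = traj.valid
    idx = np.flatnonzero(~valid)
    if idx.size == 0:
        return out
    # split invalid indices into consecutive runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        i0, i1 = run[0], run[-1]
        if len(run) > max_gap or i0 == 0 or i1 == traj.n - 1:
            continue
        lo, hi = i0 - 1, i1 + 1
        if not (valid[lo] and valid[hi]):
            continue
        frac = (traj.t[run] - traj.t[lo]) / (traj.t[hi] - traj.t[lo])
        out.pos[run] = traj.pos[lo] + frac[:, None] * (traj.pos[hi] - traj.pos[lo])
        out.valid[run] = True
    return out


def smooth_positions(traj: Trajectory, window: int) -> Trajectory:
    """Centered moving average over valid samples within ``window`` frames.

    ``window`` must be odd; 1 is the identity.  Near the edges (and next to
    dropouts) the average runs over the valid samples actually present in
    the window.  Invalid samples are left untouched.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    out = traj.copy()
    if window == 1:
        return out
    kernel = np.ones(window)
    weights = traj.valid.astype(float)
    counts = np.convolve(weights, kernel, mode="same")
    for j in range(3):
        sums = np.convolve(traj.pos[:, j] * weights, kernel, mode="same")
        with np.errstate(invalid="ignore"):
            avg = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        out.pos[traj.valid, j] = avg[traj.valid]
    return out
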