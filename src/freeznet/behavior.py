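"""Freezing / erratic-movement classification from trajectory kinematics.

Adult zebrafish respond to conspecific alarm substance with two stereotyped
fear behaviors: freezing (near-immobility sustained beyond a minimum
duration) and erratic movement (fast zig-zag darting with sharp direction
changes).  This module derives per-frame kinematics (3D speed, horizontal
turn angle) from a :class:`~freeznet.trajectory_io.Trajectory`, detects
bouts of each behavior with explicit, configurable thresholds, and
summarizes percent time per behavior over the standard protocol intervals:
a 5-min baseline, the first 5 min after stimulus onset, and three 10-min
test bins.

Thresholds live in :class:`ClassifierParams` rather than constants: the
defaults are conventional adult-zebrafish criteria (freeze below 0.5 cm/s
for at least 2 s; erratic at or above 10 cm/s with mean turning of at least
45 degrees over a 1 s window) and every study should confirm them against
its own arena and frame rate.

Tie-breaking is fixed so results are reproducible: freezing uses strict
``<`` on speed, erratic uses ``>=`` on both speed and turning.  Because
``freeze_speed_max < erratic_speed_min`` is enforced, freezing and erratic
bouts can never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory

__all__ = [
    "KinematicsSeries",
    "Bout",
    "ClassifierParams",
    "BinnedBehavior",
    "UndefinedIntervalError",
    "compute_kinematics",
    "detect_freezing",
    "detect_erratic",
    "percent_time",
    "bin_behavior",
    "INTERVAL_NAMES",
    "protocol_intervals",
]

FREEZING = "freezing"
ERRATIC = "erratic"
BEHAVIORS = (FREEZING, ERRATIC)

#: Protocol interval names in reporting order.
INTERVAL_NAMES = ("baseline", "post5", "bin1", "bin2", "bin3")


class UndefinedIntervalError(ValueError):
    """Raised when a percent-time denominator has zero valid time."""


class Bout(NamedTuple):
    """A contiguous interval of one behavior, in seconds, half-open."""

    behavior: str
    start: float
    stop: float


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the freezing / erratic classifier.

    freeze_speed_max : cm/s, speed strictly below this counts toward freezing
    freeze_min_dur : s, minimum merged-run duration for a freezing bout
    erratic_speed_min : cm/s, speed at or above this counts toward erratic
    erratic_turn_min : degrees, windowed mean turn angle threshold
    erratic_window : s, centered window for the turn-angle average
    merge_gap : s, same-behavior runs closer than this are merged
    """

    freeze_speed_max: float = 0.5
    freeze_min_dur: float = 2.0
    erratic_speed_min: float = 10.0
    erratic_turn_min: float = 45.0
    erratic_window: float = 1.0
    merge_gap: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "freeze_speed_max",
            "freeze_min_dur",
            "erratic_speed_min",
            "erratic_turn_min",
            "erratic_window",
            "merge_gap",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.freeze_speed_max < self.erratic_speed_min:
            raise ValueError("freeze_speed_max must be < erratic_speed_min")


@dataclass
class KinematicsSeries:
    """Per-frame kinematics aligned to a trajectory's timeline.

    ``speed`` is the 3D displacement over one inter-frame interval times the
    frame rate (cm/s); ``turn_angle`` the unsigned angle (degrees, 0-180)
    between consecutive horizontal-plane displacement vectors.  ``valid``
    marks samples whose speed is defined (both contributing positions
    tracked); ``turn_valid`` additionally requires the next position and
    nonzero horizontal displacements.
    """

    t: np.ndarray
    speed: np.ndarray
    turn_angle: np.ndarray
    valid: np.ndarray
    turn_valid: np.ndarray
    frame_rate: float

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def compute_kinematics(traj: Trajectory) -> KinematicsSeries:
    """Derive speed and horizontal turn angle per frame.

    ``speed[i]`` uses the backward difference ``pos[i] - pos[i-1]``; the
    first frame inherits the first computable value so bouts can cover the
    recording start.  ``turn_angle[i]`` is the angle between the (x, y)
    displacements entering and leaving sample ``i``; it is 0 (and marked
    undefined) where either displacement vanishes.  Vertical motion
    contributes to speed only.
    """
    n = traj.n
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    # require >= 3 consecutive valid samples somewhere
    run = best = 0
    for v in traj.valid:
        run = run + 1 if v else 0
        best = max(best, run)
    if best < 3:
        raise ValueError("need at least 3 consecutive valid samples")

    disp = np.diff(traj.pos, axis=0)  # (n-1, 3), step i -> i+1
    step_valid = traj.valid[:-1] & traj.valid[1:]

    speed = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    speed[1:] = np.linalg.norm(disp, axis=1) * traj.frame_rate
    valid[1:] = step_valid
    speed[0], valid[0] = speed[1], valid[1]  # boundary fill

    d2 = disp[:, :2]
    norms = np.linalg.norm(d2, axis=1)
    turn = np.zeros(n)
    turn_valid = np.zeros(n, dtype=bool)
    u, v = d2[:-1], d2[1:]  # entering / leaving sample i (i = 1..n-2)
    nu, nv = norms[:-1], norms[1:]
    defined = step_valid[:-1] & step_valid[1:] & (nu > 0) & (nv > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / np.where(nu * nv > 0, nu * nv, 1.0)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    turn[1:-1] = np.where(defined, ang, 0.0)
    turn_valid[1:-1] = defined

    return KinematicsSeries(
        t=traj.t.copy(),
        speed=speed,
        turn_angle=turn,
        valid=valid,
        turn_valid=turn_valid,
        frame_rate=traj.frame_rate,
    )


def _mask_to_runs(mask: np.ndarray, t: np.ndarray, dt: float) -> list[tuple[float, float]]:
    """Maximal True runs of ``mask`` as [t_start, t_stop) intervals."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [
        (float(t[run[0]]), float(t[run[-1]]) + dt) for run in np.split(idx, splits)
    ]


def _merge_runs(
    runs: list[tuple[float, float]], merge_gap: float
) -> list[tuple[float, float]]:
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= merge_gap + 1e-9:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def detect_freezing(kin: KinematicsSeries, params: ClassifierParams) -> list[Bout]:
    """Freezing bouts: merged sub-threshold-speed runs >= ``freeze_min_dur``.

    Runs of ``speed < freeze_speed_max`` (on valid samples) separated by at
    most ``merge_gap`` seconds are merged first; merged runs shorter than
    ``freeze_min_dur`` are discarded.  Dropout spans longer than
    ``merge_gap`` therefore break bouts.
    """
    below = kin.valid & (kin.speed < params.freeze_speed_max)
    runs = _merge_runs(_mask_to_runs(below, kin.t, kin.dt), params.merge_gap)
    return [
        Bout(FREEZING, start, stop)
        for start, stop in runs
        if stop - start >= params.freeze_min_dur - 1e-9
    ]


def detect_erratic(kin: KinematicsSeries, params: ClassifierParams) -> list[Bout]:
    """Erratic bouts: fast frames with sustained sharp turning.

    A frame qualifies when ``speed >= erratic_speed_min`` and the mean turn
    angle over the centered ``erratic_window`` (valid turn samples only) is
    at least ``erratic_turn_min``.  Qualifying runs are merged across gaps
    of at most ``merge_gap``.
    """
    w = int(round(params.erratic_window * kin.frame_rate))
    w = max(1, w) | 1  # odd, >= 1
    kernel = np.ones(w)
    tv = kin.turn_valid.astype(float)
    counts = np.convolve(tv, kernel, mode="same")
    sums = np.convolve(kin.turn_angle * tv, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        mean_turn = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    mark = (
        kin.valid
        & (kin.speed >= params.erratic_speed_min)
        & (counts > 0)
        & (mean_turn >= params.erratic_turn_min)
    )
    runs = _merge_runs(_mask_to_runs(mark, kin.t, kin.dt), params.merge_gap)
    return [Bout(ERRATIC, start, stop) for start, stop in runs]


def percent_time(
    bouts: Sequence[Bout],
    behavior: str,
    interval: tuple[float, float],
    t: np.ndarray,
    valid: np.ndarray,
    frame_rate: float,
) -> float:
    """Percent of valid time within ``interval`` spent in ``behavior``.

    Each frame occupies ``[t_i, t_i + dt)``.  The numerator is the exact
    overlap of valid frames with both the interval and the behavior's bouts
    (bouts straddling a boundary contribute pro-rata); the denominator is
    the valid time inside the interval.

    Raises
    ------
    UndefinedIntervalError
        If no valid time falls inside the interval.
    """
    a, b = interval
    if not b > a:
        raise ValueError("interval stop must be > start")
    dt = 1.0 / frame_rate
    t = np.asarray(t, dtype=float)
    frame_ov = np.clip(np.minimum(t + dt, b) - np.maximum(t, a), 0.0, None)
    frame_ov[~valid] = 0.0
    denom = frame_ov.sum()
    if denom <= 0:
        raise UndefinedIntervalError(
            f"no valid time in interval [{a}, {b}) for behavior {behavior!r}"
        )
    num = 0.0
    for bout in bouts:
        if bout.behavior != behavior:
            continue
        lo, hi = max(bout.start, a), min(bout.stop, b)
        if hi <= lo:
            continue
        ov = np.clip(np.minimum(t + dt, hi) - np.maximum(t, lo), 0.0, None)
        num += ov[valid].sum()
    return 100.0 * num / denom


def protocol_intervals(onset: float) -> dict[str, tuple[float, float]]:
    """Standard protocol intervals keyed by name.

    5-min baseline before onset; first 5 min after onset; three consecutive
    10-min test bins covering the 30-min test.
    """
    return {
        "baseline": (0.0, onset),
        "post5": (onset, onset + 300.0),
        "bin1": (onset, onset + 600.0),
        "bin2": (onset + 600.0, onset + 1200.0),
        "bin3": (onset + 1200.0, onset + 1800.0),
    }


@dataclass
class BinnedBehavior:
    """Per-fish percent time per (behavior, protocol interval).

    ``pct`` maps ``(behavior, interval_name)`` to percent of valid time;
    entries are NaN when the interval holds no valid time.  ``coverage``
    is the fraction of each interval covered by valid samples.
    """

    fish_id: str
    treatment: str
    pct: dict[tuple[str, str], float]
    coverage: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fish_id": self.fish_id,
                "treatment": self.treatment,
                "behavior": behavior,
                "interval": name,
                "pct": self.pct[(behavior, name)],
                "coverage": self.coverage[name],
            }
            for behavior in BEHAVIORS
            for name in INTERVAL_NAMES
        ]
        return pd.DataFrame(rows)


def bin_behavior(bouts: Sequence[Bout], traj: Trajectory) -> BinnedBehavior:
    """Summarize bouts into the protocol's percent-time table.

    Produces both behaviors over baseline, the first 5 min post-onset and
    exactly three 10-min test bins.  A trajectory ending before the protocol
    does is flagged with a warning; intervals without valid time get NaN and
    a warning rather than a silent zero.
    """
    intervals = protocol_intervals(traj.protocol_onset)
    warnings: list[str] = []
    protocol_end = traj.protocol_onset + 1800.0
    if traj.duration < protocol_end - 1e-9:
        warnings.append(
            f"trajectory ends at {traj.duration:.1f} s, before protocol end "
            f"{protocol_end:.1f} s; later bins are partial or missing"
        )
    dt = traj.dt
    pct: dict[tuple[str, str], float] = {}
    coverage: dict[str, float] = {}
    for name, (a, b) in intervals.items():
        ov = np.clip(np.minimum(traj.t + dt, b) - np.maximum(traj.t, a), 0.0, None)
        coverage[name] = float(ov[traj.valid].sum() / (b - a))
        for behavior in BEHAVIORS:
            try:
                pct[(behavior, name)] = percent_time(
                    bouts, behavior, (a, b), traj.t, traj.valid, traj.frame_rate
                )
            except UndefinedIntervalError:
                pct[(behavior, name)] = float("nan")
                if f"interval {name!r} has no valid time" not in warnings:
                    warnings.append(f"interval {name!r} has no valid time")
    return BinnedBehavior(
        fish_id=traj.fish_id,
        treatment=traj.treatment,
        pct=pct,
        coverage=coverage,
        warnings=warnings,
    )
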