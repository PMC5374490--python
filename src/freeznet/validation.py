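"""Agreement between the automated classifier and a human observer.

Automated scoring of freezing is only trustworthy if it reproduces what a
trained observer scores from the same recordings.  The primary metric here
is the Pearson correlation between per-fish freezing percentages (automated
vs. observer) over the 30-min test — the granularity at which treatment
effects are analyzed.  Frame-level Cohen's kappa is offered as a stricter
secondary metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObserverLog",
    "ZeroVarianceError",
    "load_observer_log",
    "observer_percent",
    "observer_agreement",
    "frame_kappa",
]


class ZeroVarianceError(ValueError):
    """Raised when a correlation is undefined because a vector is constant."""


@dataclass
class ObserverLog:
    """Human-scored behavior events for one fish.

    ``events`` holds ``(behavior, start_s, stop_s)`` tuples; same-behavior
    events must not overlap.
    """

    fish_id: str
    events: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        by_behavior: dict[str, list[tuple[float, float]]] = {}
        for behavior, start, stop in self.events:
            if not stop > start:
                raise ValueError(
                    f"{self.fish_id}: event stop must be > start ({start}, {stop})"
                )
            by_behavior.setdefault(behavior, []).append((start, stop))
        for behavior, spans in by_behavior.items():
            spans.sort()
            for (a0, b0), (a1, _) in zip(spans, spans[1:]):
                if a1 < b0 - 1e-9:
                    raise ValueError(
                        f"{self.fish_id}: overlapping {behavior!r} events "
                        f"([{a0}, {b0}) and starting {a1})"
                    )


def load_observer_log(path) -> dict[str, ObserverLog]:
    """Load a ``fish_id,behavior,start_s,stop_s`` CSV, one log per fish.

    Overlapping same-behavior events raise ``ValueError``.  A fish with no
    rows simply has no log; an empty event list is valid and scores 0%.
    """
    df = pd.read_csv(path)
    required = {"fish_id", "behavior", "start_s", "stop_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    logs: dict[str, ObserverLog] = {}
    for fish_id, grp in df.groupby("fish_id", sort=True):
        events = [
            (str(r.behavior), float(r.start_s), float(r.stop_s))
            for r in grp.itertuples()
        ]
        logs[str(fish_id)] = ObserverLog(fish_id=str(fish_id), events=events)
    return logs


def observer_percent(
    log: ObserverLog, behavior: str, interval: tuple[float, float]
) -> float:
    """Percent of ``interval`` covered by the observer's ``behavior`` events."""
    a, b = interval
    if not b > a:
        raise ValueError("interval stop must be > start")
    total = sum(
        max(0.0, min(stop, b) - max(start, a))
        for beh, start, stop in log.events
        if beh == behavior
    )
    return 100.0 * total / (b - a)


class AgreementResult(NamedTuple):
    r: float
    p: float
    n: int


def observer_agreement(
    auto: Sequence[float], human: Sequence[float]
) -> AgreementResult:
    """Pearson correlation between automated and observer per-fish percentages.

    Two-sided p-value from the t transform with n - 2 degrees of freedom
    (scipy's default).  Requires at least 3 finite pairs and nonzero
    variance in both vectors.
    """
    a = np.asarray(auto, dtype=float)
    h = np.asarray(human, dtype=float)
    if a.shape != h.shape or a.ndim != 1:
        raise ValueError("auto and human must be 1-D vectors of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 fish for a correlation")
    if not (np.isfinite(a).all() and np.isfinite(h).all()):
        raise ValueError("non-finite percentages")
    if np.ptp(a) == 0 or np.ptp(h) == 0:
        raise ZeroVarianceError("correlation undefined: constant vector")
    r, p = stats.pearsonr(a, h)
    return AgreementResult(r=float(r), p=float(p), n=len(a))


def frame_kappa(auto_states: np.ndarray, human_states: np.ndarray) -> float:
    """Cohen's kappa between two per-frame binary (or categorical) labelings."""
    a = np.asarray(auto_states)
    h = np.asarray(human_states)
    if a.shape != h.shape:
        raise ValueError("labelings must align frame-by-frame")
    labels = np.union1d(np.unique(a), np.unique(h))
    n = len(a)
    po = float(np.mean(a == h))
    pe = sum(np.mean(a == c) * np.mean(h == c) for c in labels)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)
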