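"""Synthetic study data with the statistical structure the analysis assumes.

No raw tracking, observer or qPCR data are deposited for this kind of
study, so every pipeline stage is exercised against generators that
emulate the experiment:

* **Trajectories** — a focal fish behaving as a 3-state continuous-time
  Markov chain over {swim, erratic, freeze} whose transition rates switch
  at stimulus onset (5-min baseline, 30-min test).  Freezing entry is much
  higher after alarm-substance onset for fish tested alone than for fish
  with shoal cues (social buffering): the default configurations put
  post-onset freezing occupancy near 50% (alone) vs 20% (buffered).
  Positions follow per-state kinematics — a persistent random walk while
  swimming, fast low-persistence darting while erratic, a held position
  with millimetre jitter while freezing — inside reflective arena walls,
  with optional tracking noise and dropouts.
* **Observer logs** — ground-truth freezing runs degraded by a miss rate
  and Gaussian boundary jitter, for validating the classifier the way a
  human-scored event log would.
* **Expression tables** — fish x nucleus log2 c-fos levels drawn from a
  multivariate normal with a configurable inter-nucleus correlation
  structure, emitted as Ct pairs against a fixed 18S reference so they
  round-trip exactly through the 2^-dCt computation.  Factories provide
  the *decoupled* structure (Dm-Vs-POA correlated, Vv independent — the
  social-buffering signature) and a fully *coupled* control structure.

Everything is seeded and deterministic: the same seed yields bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import linalg

from .expression import NUCLEI, REFERENCE_GENE, TARGET_GENE
from .trajectory_io import ArenaCalibration, Trajectory, write_trajectory
from .validation import ObserverLog

__all__ = [
    "STATES",
    "SWIM",
    "ERRATIC_STATE",
    "FREEZE",
    "StateKinematics",
    "TrajectorySimConfig",
    "ExpressionSimConfig",
    "alone_config",
    "buffered_config",
    "decoupled_structure",
    "coupled_structure",
    "expression_config",
    "rate_matrix",
    "stationary_distribution",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_observer",
    "simulate_expression",
    "CohortFish",
]

STATES = ("swim", "erratic", "freeze")
SWIM, ERRATIC_STATE, FREEZE = 0, 1, 2
_STATE_INDEX = {name: i for i, name in enumerate(STATES)}

Rates = dict[tuple[str, str], float]


@dataclass(frozen=True)
class StateKinematics:
    """Per-state movement parameters (cm, s, degrees).

    Swim speeds sit comfortably between the freezing (0.5 cm/s) and erratic
    (10 cm/s) thresholds; erratic speeds well above with near-uniform
    heading changes; freezing is a held position with sub-millimetre body
    jitter.  ``vertical_step_sd`` is the per-frame z random-walk step while
    moving.
    """

    swim_speed_mean: float = 3.0
    swim_speed_sd: float = 1.0
    swim_turn_sd: float = 12.0
    erratic_speed_mean: float = 18.0
    erratic_speed_sd: float = 4.0
    freeze_jitter_sd: float = 0.003
    vertical_step_sd: float = 0.02


def _default_rates_pre() -> Rates:
    # quiet baseline: rare, brief freezing and darting
    return {
        ("swim", "freeze"): 0.002,
        ("freeze", "swim"): 0.5,
        ("swim", "erratic"): 0.001,
        ("erratic", "swim"): 1.0,
    }


def _alone_rates_post() -> Rates:
    # alarm substance, no conspecific cues: ~50% freezing occupancy
    return {
        ("swim", "freeze"): 0.10,
        ("freeze", "swim"): 0.095,
        ("swim", "erratic"): 0.03,
        ("erratic", "swim"): 1.0,
    }


def _buffered_rates_post() -> Rates:
    # alarm substance with shoal cues: buffered, ~20% freezing occupancy
    return {
        ("swim", "freeze"): 0.04,
        ("freeze", "swim"): 0.16,
        ("swim", "erratic"): 0.015,
        ("erratic", "swim"): 1.0,
    }


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Configuration of the 3-state behavioral trajectory simulator.

    ``rates_pre`` / ``rates_post`` are transition rates (per second) of the
    continuous-time Markov chain before and after ``onset_s``.  Tracking
    noise is additive iid Gaussian on every coordinate; dropouts are iid
    per frame.
    """

    treatment: str = "Alone_AS"
    duration_s: float = 2100.0
    onset_s: float = 300.0
    frame_rate: float = 30.0
    kin: StateKinematics = field(default_factory=StateKinematics)
    rates_pre: Rates = field(default_factory=_default_rates_pre)
    rates_post: Rates = field(default_factory=_alone_rates_post)
    noise_sd: float = 0.01
    dropout_p: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        for rates in (self.rates_pre, self.rates_post):
            for (src, dst), rate in rates.items():
                if src not in STATES or dst not in STATES or src == dst:
                    raise ValueError(f"bad transition ({src!r}, {dst!r})")
                if rate < 0:
                    raise ValueError("rates must be >= 0")
        if not 0 <= self.dropout_p <= 1:
            raise ValueError("dropout_p must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def alone_config(**overrides) -> TrajectorySimConfig:
    """Fish exposed to alarm substance with no conspecific cues."""
    return TrajectorySimConfig(treatment="Alone_AS", **overrides)


def buffered_config(**overrides) -> TrajectorySimConfig:
    """Fish exposed to alarm substance with shoal cues (social buffering)."""
    return TrajectorySimConfig(
        treatment="SB_AS", rates_post=_buffered_rates_post(), **overrides
    )


def rate_matrix(rates: Rates) -> np.ndarray:
    """Generator matrix Q of the 3-state chain (rows sum to zero)."""
    Q = np.zeros((3, 3))
    for (src, dst), rate in rates.items():
        Q[_STATE_INDEX[src], _STATE_INDEX[dst]] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(rates: Rates) -> np.ndarray:
    """Stationary distribution pi of the chain (pi Q = 0, pi summing to 1)."""
    Q = rate_matrix(rates)
    ns = linalg.null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError("chain is reducible; stationary distribution not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("invalid stationary distribution")
    return np.clip(pi, 0.0, None)


def _simulate_states(cfg: TrajectorySimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame state codes from the epoch-switched chain (Gillespie)."""
    n = int(round(cfg.duration_s * cfg.frame_rate))
    Q_pre = rate_matrix(cfg.rates_pre)
    Q_post = rate_matrix(cfg.rates_post)
    if not (np.any(Q_pre) or np.any(Q_post)):
        raise ValueError("degenerate all-zero rate matrices")
    seg_starts = [0.0]
    seg_states = [SWIM]
    t, state = 0.0, SWIM
    T = cfg.duration_s
    while t < T:
        Q = Q_pre if t < cfg.onset_s else Q_post
        out_rate = -Q[state, state]
        hold = rng.exponential(1.0 / out_rate) if out_rate > 0 else np.inf
        # piecewise-constant rates: truncate holding times at the onset
        if t < cfg.onset_s <= t + hold:
            t = cfg.onset_s
            continue
        t = t + hold
        if t >= T:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(3, p=probs))
        seg_starts.append(t)
        seg_states.append(state)
    frame_times = np.arange(n) / cfg.frame_rate
    idx = np.searchsorted(np.asarray(seg_starts), frame_times, side="right") - 1
    return np.asarray(seg_states, dtype=np.int8)[idx]


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded 1-D path into [lo, hi] (triangle-wave map)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    return lo + np.where(y <= width, y, 2.0 * width - y)


def _positions_from_states(
    states: np.ndarray,
    cfg: TrajectorySimConfig,
    bounds: tuple[tuple[float, float], ...],
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(states)
    kin = cfg.kin
    swim = states == SWIM
    erratic = states == ERRATIC_STATE
    freeze = states == FREEZE
    moving = ~freeze

    speed = np.zeros(n)
    speed[swim] = np.clip(
        rng.normal(kin.swim_speed_mean, kin.swim_speed_sd, swim.sum()), 0.0, None
    )
    speed[erratic] = np.clip(
        rng.normal(kin.erratic_speed_mean, kin.erratic_speed_sd, erratic.sum()),
        0.0,
        None,
    )
    turn = np.zeros(n)
    turn[swim] = rng.normal(0.0, kin.swim_turn_sd, swim.sum())
    turn[erratic] = rng.uniform(-180.0, 180.0, erratic.sum())

    heading = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(np.radians(turn))
    step = speed / cfg.frame_rate
    dz = np.where(moving, rng.normal(0.0, kin.vertical_step_sd, n), 0.0)
    d = np.column_stack((step * np.cos(heading), step * np.sin(heading), dz))

    pos = np.empty((n, 3))
    for axis, (lo, hi) in enumerate(bounds):
        start = 0.5 * (lo + hi)
        pos[:, axis] = _fold(start + np.cumsum(d[:, axis]), lo, hi)

    if kin.freeze_jitter_sd > 0:
        pos[freeze] += rng.normal(0.0, kin.freeze_jitter_sd, (int(freeze.sum()), 3))
    if cfg.noise_sd > 0:
        pos += rng.normal(0.0, cfg.noise_sd, (n, 3))
    for axis, (lo, hi) in enumerate(bounds):
        np.clip(pos[:, axis], lo, hi, out=pos[:, axis])
    return pos


def simulate_trajectory(
    cfg: TrajectorySimConfig,
    *,
    calib: ArenaCalibration | None = None,
    rng: np.random.Generator | None = None,
    fish_id: str = "sim",
) -> tuple[Trajectory, np.ndarray]:
    """Simulate one focal fish; returns the trajectory and per-frame truth.

    Truth is an int8 array of state codes (:data:`SWIM`,
    :data:`ERRATIC_STATE`, :data:`FREEZE`) aligned to the trajectory's
    frames.  With ``rng`` unset, ``cfg.seed`` seeds a fresh generator, so
    identical configs give bit-identical outputs.
    """
    if calib is None:
        calib = ArenaCalibration(frame_rate=cfg.frame_rate)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    states = _simulate_states(cfg, rng)
    pos = _positions_from_states(states, cfg, calib.arena_bounds, rng)
    n = len(states)
    valid = rng.random(n) >= cfg.dropout_p
    traj = Trajectory(
        fish_id=fish_id,
        treatment=cfg.treatment,
        t=np.arange(n) / cfg.frame_rate,
        pos=pos,
        valid=valid,
        frame_rate=cfg.frame_rate,
        protocol_onset=cfg.onset_s,
    )
    return traj, states


class CohortFish(NamedTuple):
    fish_id: str
    treatment: str
    trajectory: Trajectory
    states: np.ndarray


def _scale_rates(rates: Rates, factors: dict[tuple[str, str], float]) -> Rates:
    return {key: rate * factors.get(key, 1.0) for key, rate in rates.items()}


def simulate_cohort(
    cfgs: dict[str, TrajectorySimConfig] | list[TrajectorySimConfig],
    n_per_group: int,
    *,
    seed: int | None = None,
    rate_effect_sd: float = 0.3,
    calib: ArenaCalibration | None = None,
    out_dir=None,
) -> list[CohortFish]:
    """Independent fish per treatment with lognormal rate heterogeneity.

    Each fish multiplies every transition rate by its own lognormal factor
    (sigma = ``rate_effect_sd``; 0 means all fish share the configured
    rates exactly).  With ``out_dir`` set, trajectories are written as
    ``<treatment>__<fish>.csv`` in the CSV dialect
    :func:`freeznet.trajectory_io.read_trajectory` consumes.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if isinstance(cfgs, dict):
        cfgs = [replace(cfg, treatment=name) for name, cfg in cfgs.items()]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cfgs) * n_per_group)
    cohort: list[CohortFish] = []
    k = 0
    for cfg in cfgs:
        for i in range(n_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            keys = sorted(set(cfg.rates_pre) | set(cfg.rates_post))
            factors = {
                key: float(rng.lognormal(0.0, rate_effect_sd)) if rate_effect_sd > 0 else 1.0
                for key in keys
            }
            fish_cfg = replace(
                cfg,
                rates_pre=_scale_rates(cfg.rates_pre, factors),
                rates_post=_scale_rates(cfg.rates_post, factors),
            )
            fish_id = f"{cfg.treatment}__f{i:02d}"
            traj, states = simulate_trajectory(
                fish_cfg, calib=calib, rng=rng, fish_id=fish_id
            )
            cohort.append(CohortFish(fish_id, cfg.treatment, traj, states))
            if out_dir is not None:
                import os

                write_trajectory(traj, os.path.join(str(out_dir), f"{fish_id}.csv"))
    return cohort


def simulate_observer(
    states: np.ndarray,
    frame_rate: float,
    *,
    miss_rate: float = 0.0,
    boundary_jitter_s: float = 0.0,
    seed: int | None = None,
    fish_id: str = "sim",
) -> ObserverLog:
    """Human-observer-style freezing log derived from ground-truth states.

    True freezing runs become events; each is dropped with probability
    ``miss_rate`` and its boundaries perturbed by Gaussian jitter.  Events
    are kept chronological and non-overlapping after jitter.
    """
    if not 0 <= miss_rate <= 1:
        raise ValueError("miss_rate must be in [0, 1]")
    if boundary_jitter_s < 0:
        raise ValueError("boundary_jitter_s must be >= 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    freeze = np.asarray(states) == FREEZE
    idx = np.flatnonzero(freeze)
    events: list[tuple[str, float, float]] = []
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        T = len(states) * dt
        prev_stop = 0.0
        for run in np.split(idx, splits):
            start, stop = run[0] * dt, (run[-1] + 1) * dt
            if rng.random() < miss_rate:
                continue
            if boundary_jitter_s > 0:
                start += rng.normal(0.0, boundary_jitter_s)
                stop += rng.normal(0.0, boundary_jitter_s)
            start = max(start, prev_stop, 0.0)
            stop = min(stop, T)
            if stop <= start:
                continue
            events.append(("freezing", float(start), float(stop)))
            prev_stop = stop
    return ObserverLog(fish_id=fish_id, events=events)


def decoupled_structure(r: float | tuple[float, float, float] = 0.7) -> np.ndarray:
    """Dm-Vs-POA mutually correlated; Vv independent of all.

    The co-activation signature of buffered fish: the septum/accumbens
    homologue decouples from the fear-circuit nuclei.  Node order follows
    :data:`freeznet.expression.NUCLEI` (Dm, Vv, Vs, POA).

    ``r`` is either one coupling shared by all three pairs, or a
    ``(Dm-Vs, Dm-POA, Vs-POA)`` triple.  Distinct values break the
    exchangeability of the three coupled nuclei — real co-activation
    matrices are never exactly exchangeable, and a permutation test can
    only tell two samples of the *same* structure apart from relabelings
    when the structure has no nontrivial automorphism (see the network
    module's QAP notes).
    """
    rs = (r, r, r) if np.isscalar(r) else tuple(r)
    if len(rs) != 3:
        raise ValueError("r must be a scalar or a (Dm-Vs, Dm-POA, Vs-POA) triple")
    C = np.eye(4)
    for (a, b), value in zip((("Dm", "Vs"), ("Dm", "POA"), ("Vs", "POA")), rs):
        i, j = NUCLEI.index(a), NUCLEI.index(b)
        C[i, j] = C[j, i] = value
    return C


def coupled_structure(r: float = 0.7) -> np.ndarray:
    """All four nuclei mutually correlated at ``r``."""
    C = np.full((4, 4), r)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration of the qPCR expression simulator.

    ``mean_log2`` / ``sd_log2`` are per-nucleus moments of log2 relative
    c-fos expression (vs. the 18S reference); ``corr`` the target
    inter-nucleus correlation matrix (symmetric positive-definite, unit
    diagonal).  ``ref_ct`` is the fixed reference-gene Ct — 18S is highly
    abundant so it amplifies early.
    """

    treatment: str = "SB_AS"
    n_fish: int = 10
    nuclei: tuple[str, ...] = NUCLEI
    mean_log2: tuple[float, ...] = (-8.0, -8.0, -8.0, -8.0)
    sd_log2: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    corr: np.ndarray = field(default_factory=decoupled_structure)
    ref_ct: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        k = len(self.nuclei)
        corr = np.asarray(self.corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"corr must be {k}x{k}")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("corr must be symmetric with unit diagonal")
        if len(self.mean_log2) != k or len(self.sd_log2) != k:
            raise ValueError("mean_log2/sd_log2 must match nuclei")
        if any(s <= 0 for s in self.sd_log2):
            raise ValueError("sd_log2 must be positive")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")


def expression_config(
    treatment: str,
    corr: np.ndarray,
    *,
    n_fish: int = 10,
    seed: int | None = None,
    **overrides,
) -> ExpressionSimConfig:
    return ExpressionSimConfig(
        treatment=treatment, corr=corr, n_fish=n_fish, seed=seed, **overrides
    )


def simulate_expression(
    cfg: ExpressionSimConfig,
    *,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Draw a Ct table whose relative quantities have the target structure.

    log2 expression per fish is multivariate normal with the configured
    moments and correlation; Ct(c-fos) = ref_ct - log2(expression) against
    a fixed Ct(18s) = ref_ct, so ``2**-dCt`` recovers the generated
    expression exactly.

    Returns a tidy ``fish_id,treatment,nucleus,gene,ct`` DataFrame, plus
    the fish x nucleus expression grid when ``return_truth``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    corr = np.asarray(cfg.corr, dtype=float)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("corr must be positive-definite") from None
    k = len(cfg.nuclei)
    z = rng.standard_normal((cfg.n_fish, k))
    log2_expr = np.asarray(cfg.mean_log2) + np.asarray(cfg.sd_log2) * (z @ L.T)
    expression = np.power(2.0, log2_expr)

    rows = []
    for i in range(cfg.n_fish):
        fish_id = f"{cfg.treatment}__f{i:02d}"
        for j, nucleus in enumerate(cfg.nuclei):
            ct_target = cfg.ref_ct - log2_expr[i, j]
            rows.append(
                {
                    "fish_id": fish_id,
                    "treatment": cfg.treatment,
                    "nucleus": nucleus,
                    "gene": TARGET_GENE,
                    "ct": float(ct_target),
                }
            )
            rows.append(
                {
                    "fish_id": fish_id,
                    "treatment": cfg.treatment,
                    "nucleus": nucleus,
                    "gene": REFERENCE_GENE,
                    "ct": float(cfg.ref_ct),
                }
            )
    ct = pd.DataFrame(rows)
    if return_truth:
        truth = pd.DataFrame(
            expression,
            index=[f"{cfg.treatment}__f{i:02d}" for i in range(cfg.n_fish)],
            columns=list(cfg.nuclei),
        )
        return ct, truth
    return ct
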