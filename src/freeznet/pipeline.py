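"""End-to-end orchestration: config in, reproducible report bundle out.

``run_pipeline`` composes the stages — trajectory reading and cleaning,
behavior classification and protocol binning, observer validation, qPCR
relative expression with group statistics, and co-activation network
construction and QAP comparison — skipping (with a logged notice, not a
failure) any stage whose inputs are absent from the config.  All tabular
outputs are CSV; a machine-readable manifest records the config hash, the
seed and a digest of every output so a run can be verified byte-for-byte.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .behavior import (
    ClassifierParams,
    bin_behavior,
    compute_kinematics,
    detect_erratic,
    detect_freezing,
    percent_time,
)
from .expression import group_expression_test, read_ct_table, relative_expression
from .network import coactivation_matrix, compare_networks, eigenvector_centrality, network_density
from .trajectory_io import (
    ArenaCalibration,
    interpolate_gaps,
    read_trajectory,
    smooth_positions,
)
from .validation import load_observer_log, observer_agreement, observer_percent

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("freeznet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    ``trajectories`` may be a glob pattern, a directory, or an explicit
    list of CSV paths.  Treatment labels are taken from the filename
    convention ``<treatment>__<fish>.csv`` (the simulator writes this
    dialect).  ``qap_pairs`` / ``expression_comparisons`` declare which
    treatment pairs are tested (and thus the Holm family); ``None`` means
    all pairs.
    """

    out_dir: str
    trajectories: str | list[str] | None = None
    observer_logs: str | None = None
    ct_table: str | None = None
    frame_rate: float = 30.0
    unit_scale: float = 1.0
    arena_bounds: tuple[tuple[float, float], ...] = (
        (0.0, 30.0),
        (0.0, 15.0),
        (0.0, 25.0),
    )
    onset_s: float = 300.0
    max_gap: int = 5
    smooth_window: int = 5
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    efficiency: float = 2.0
    calibrator: str | None = None
    expression_comparisons: list[tuple[str, str]] | None = None
    qap_pairs: list[tuple[str, str]] | None = None
    alpha: float = 0.05
    significant_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierParams(**self.classifier)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "arena_bounds" in raw:
            raw["arena_bounds"] = tuple(tuple(b) for b in raw["arena_bounds"])
        for key in ("expression_comparisons", "qap_pairs"):
            if raw.get(key) is not None:
                raw[key] = [tuple(p) for p in raw[key]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["classifier"] = dict(self.classifier.__dict__)
        d["arena_bounds"] = [list(b) for b in self.arena_bounds]
        for key in ("expression_comparisons", "qap_pairs"):
            if d[key] is not None:
                d[key] = [list(p) for p in d[key]]
        return d

    def calibration(self) -> ArenaCalibration:
        return ArenaCalibration(
            frame_rate=self.frame_rate,
            unit_scale=self.unit_scale,
            arena_bounds=self.arena_bounds,
        )


def _resolve_trajectories(spec) -> list[str]:
    if spec is None:
        return []
    if isinstance(spec, (list, tuple)):
        return [str(p) for p in spec]
    spec = str(spec)
    if os.path.isdir(spec):
        return sorted(glob.glob(os.path.join(spec, "*.csv")))
    return sorted(glob.glob(spec))


def _split_treatment(path: str) -> tuple[str, str]:
    stem = os.path.splitext(os.path.basename(path))[0]
    if "__" in stem:
        treatment, _, _ = stem.partition("__")
        return treatment, stem
    return "", stem


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def classify_trajectory(path: str, cfg: RunConfig):
    """One trajectory through cleaning, smoothing and classification."""
    treatment, fish_id = _split_treatment(path)
    traj = read_trajectory(
        path,
        cfg.calibration(),
        fish_id=fish_id,
        treatment=treatment,
        protocol_onset=cfg.onset_s,
    )
    traj = interpolate_gaps(traj, cfg.max_gap)
    traj = smooth_positions(traj, cfg.smooth_window)
    kin = compute_kinematics(traj)
    bouts = detect_freezing(kin, cfg.classifier) + detect_erratic(kin, cfg.classifier)
    binned = bin_behavior(bouts, traj)
    return traj, bouts, binned


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage whose inputs are configured; return the manifest.

    Outputs written under ``cfg.out_dir`` (stage permitting): ``bouts.csv``,
    ``binned_behavior.csv``, ``validation.json``, ``expression_rq.csv``,
    ``expression_comparisons.csv``, ``network_edges.csv``,
    ``network_centrality.csv``, ``network_summary.csv``,
    ``network_comparisons.csv`` and ``manifest.json``.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(cfg.out_dir, name)
        df.to_csv(path, index=False)
        outputs.append(name)

    # --- behavior stage -------------------------------------------------
    traj_paths = _resolve_trajectories(cfg.trajectories)
    trajectories = {}
    bouts_by_fish = {}
    if traj_paths:
        bout_rows, binned_frames = [], []
        for path in traj_paths:
            try:
                traj, bouts, binned = classify_trajectory(path, cfg)
            except Exception as exc:
                raise PipelineError(f"behavior stage failed on {path}: {exc}") from exc
            trajectories[traj.fish_id] = traj
            bouts_by_fish[traj.fish_id] = bouts
            for bout in bouts:
                bout_rows.append(
                    {
                        "fish_id": traj.fish_id,
                        "treatment": traj.treatment,
                        "behavior": bout.behavior,
                        "start_s": bout.start,
                        "stop_s": bout.stop,
                    }
                )
            binned_frames.append(binned.to_frame())
        emit("bouts.csv", pd.DataFrame(bout_rows, columns=["fish_id", "treatment", "behavior", "start_s", "stop_s"]))
        emit("binned_behavior.csv", pd.concat(binned_frames, ignore_index=True))
    else:
        log.info("behavior stage skipped: no trajectories configured")

    # --- validation stage -----------------------------------------------
    if cfg.observer_logs and trajectories:
        try:
            logs = load_observer_log(cfg.observer_logs)
            test_end = cfg.onset_s + 1800.0
            auto, human = [], []
            for fish_id, traj in sorted(trajectories.items()):
                if fish_id not in logs:
                    continue
                auto.append(
                    percent_time(
                        bouts_by_fish[fish_id],
                        "freezing",
                        (cfg.onset_s, test_end),
                        traj.t,
                        traj.valid,
                        traj.frame_rate,
                    )
                )
                human.append(
                    observer_percent(logs[fish_id], "freezing", (cfg.onset_s, test_end))
                )
            result = observer_agreement(auto, human)
            with open(os.path.join(cfg.out_dir, "validation.json"), "w") as fh:
                json.dump(
                    {"r": result.r, "p": result.p, "n": result.n}, fh, sort_keys=True
                )
            outputs.append("validation.json")
        except Exception as exc:
            raise PipelineError(
                f"validation stage failed on {cfg.observer_logs}: {exc}"
            ) from exc
    elif cfg.observer_logs:
        log.info("validation stage skipped: no trajectories to validate")
    else:
        log.info("validation stage skipped: no observer logs configured")

    # --- expression + network stages ------------------------------------
    if cfg.ct_table:
        try:
            ct = read_ct_table(cfg.ct_table)
            expr = relative_expression(
                ct, efficiency=cfg.efficiency, calibrator=cfg.calibrator
            )
            tidy = pd.concat(
                [
                    grid.reset_index()
                    .melt(id_vars="fish_id", var_name="nucleus", value_name="rq")
                    .assign(treatment=name)
                    for name, grid in sorted(expr.items())
                ],
                ignore_index=True,
            )[["treatment", "fish_id", "nucleus", "rq"]]
            emit("expression_rq.csv", tidy)
            test = group_expression_test(expr, cfg.expression_comparisons)
            emit("expression_comparisons.csv", test.pairwise)
        except Exception as exc:
            raise PipelineError(
                f"expression stage failed on {cfg.ct_table}: {exc}"
            ) from exc

        try:
            nets = {
                name: coactivation_matrix(grid, name, log2=True)
                for name, grid in sorted(expr.items())
            }
            edges = pd.concat(
                [net.edge_table(cfg.alpha) for net in nets.values()],
                ignore_index=True,
            )
            emit("network_edges.csv", edges)
            cent_rows, summary_rows = [], []
            for name, net in nets.items():
                cent = eigenvector_centrality(
                    net, significant_only=cfg.significant_only, alpha=cfg.alpha
                )
                for node, value in cent.items():
                    cent_rows.append(
                        {"treatment": name, "node": node, "centrality": value}
                    )
                summary_rows.append(
                    {
                        "treatment": name,
                        "density": network_density(
                            net, significant_only=cfg.significant_only, alpha=cfg.alpha
                        ),
                        "n_fish": len(expr[name]),
                    }
                )
            emit("network_centrality.csv", pd.DataFrame(cent_rows))
            emit("network_summary.csv", pd.DataFrame(summary_rows))
            names = sorted(nets)
            pairs = cfg.qap_pairs or [
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
            ]
            comparisons = compare_networks(
                nets, pairs, alpha=cfg.alpha, seed=cfg.seed
            )
            emit("network_comparisons.csv", comparisons)
        except Exception as exc:
            raise PipelineError(
                f"network stage failed on {cfg.ct_table}: {exc}"
            ) from exc
    else:
        log.info("expression/network stages skipped: no Ct table configured")

    # --- manifest --------------------------------------------------------
    config_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "software": "freeznet",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {
            name: _sha256(os.path.join(cfg.out_dir, name)) for name in sorted(outputs)
        },
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest
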