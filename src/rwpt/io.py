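"""Readers/writers for the trial, metadata and metrics CSV dialects, and the
end-to-end pipeline (simulate or load -> score -> statistics).

Trials CSV: one row per pointing response, UTF-8, "." decimals, mandatory
header, angles in degrees with 6 decimals.  The pointing direction comes
either as a room-frame unit vector (``dir_x, dir_y, dir_z``) or as angles
(``azimuth_deg, polar_deg``) — exactly one representation per file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import Direction3, InvalidDirectionError, SphericalAngles, from_spherical
from .scoring import ParadigmID, PointingTrial, metrics_to_frame, score_participant
from .simulate import simulate_cohort, trials_to_frame
from .stats import report_to_markdown, run_statistics

__all__ = ["TrialsParseError", "read_trials", "write_trials", "read_metadata",
           "write_metrics", "run_pipeline"]

logger = logging.getLogger("rwpt")

_VECTOR_COLS = ("dir_x", "dir_y", "dir_z")
_ANGLE_COLS = ("azimuth_deg", "polar_deg")
_BASE_COLS = ("participant_id", "paradigm", "trial_index", "target_row", "target_col")
_UNIT_TOL = 1e-3


class TrialsParseError(ValueError):
    pass


def _frame_to_trials(df: pd.DataFrame, source: str = "<frame>") -> list[PointingTrial]:
    cols = list(df.columns)
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise TrialsParseError(f"{source}: duplicated header columns {dupes}")
    missing = [c for c in _BASE_COLS if c not in cols]
    if missing:
        raise TrialsParseError(f"{source}: missing columns {missing}")
    has_vec = all(c in cols for c in _VECTOR_COLS)
    has_ang = all(c in cols for c in _ANGLE_COLS)
    if has_vec == has_ang:
        raise TrialsParseError(
            f"{source}: exactly one direction representation required "
            f"(either {_VECTOR_COLS} or {_ANGLE_COLS})")

    trials = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = row._asdict()
        try:
            paradigm = ParadigmID(str(rec["paradigm"]))
        except ValueError:
            raise TrialsParseError(
                f"{source}: row {row_no}: unknown paradigm {rec['paradigm']!r}") from None
        target = (str(rec["target_row"]), str(rec["target_col"]))
        try:
            if has_vec:
                v = np.array([rec[c] for c in _VECTOR_COLS], dtype=float)
                if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
                    raise TrialsParseError(
                        f"{source}: row {row_no}: direction norm {np.linalg.norm(v):.4f} "
                        f"deviates from 1 beyond tolerance {_UNIT_TOL}")
                direction = Direction3(*v)
            else:
                direction = from_spherical(SphericalAngles(
                    float(rec["azimuth_deg"]), float(rec["polar_deg"])))
            trials.append(PointingTrial(str(rec["participant_id"]), paradigm,
                                        int(rec["trial_index"]), target, direction))
        except TrialsParseError:
            raise
        except (InvalidDirectionError, ValueError) as e:
            raise TrialsParseError(f"{source}: row {row_no}: {e}") from e
    return trials


def read_trials(path) -> list[PointingTrial]:
    """Read and validate a trials CSV; errors carry the offending row number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise TrialsParseError(f"{path}: duplicated header columns {dupes}")
    df = pd.read_csv(path)
    return _frame_to_trials(df, str(path))


def write_trials(trials, path) -> None:
    df = trials_to_frame(list(trials))
    for c in _VECTOR_COLS:
        df[c] = df[c].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns or "group" not in df.columns:
        raise TrialsParseError(f"{path}: metadata requires participant_id and group columns")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_metrics(metrics: pd.DataFrame, path) -> None:
    out = metrics.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.6f}" if pd.notna(v) else "")
    out.to_csv(path, index=False)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, seed: int | None = None) -> dict:
    """Full pipeline: simulate (or load) trials, score every participant, run statistics.

    Outputs under ``config.paths.output_dir``: trials.csv (when simulated),
    metrics.csv, report.json, report.md and run.log.  Deterministic given the
    config and seeds; ``seed`` overrides both the simulation master seed and
    the statistics bootstrap seed.
    """
    from . import __version__

    if seed is not None:
        config = config.model_copy(deep=True)
        config.simulation.master_seed = int(seed)
        config.statistics.seed = int(seed)

    outdir = Path(config.paths.output_dir)
    grid = config.geometry.to_grid()

    # resolve inputs before creating any output
    if config.paths.trials_csv:
        trials = read_trials(config.paths.trials_csv)
        if not config.paths.metadata_csv:
            raise ValueError("metadata_csv is required when trials_csv is given")
        metadata = read_metadata(config.paths.metadata_csv)
        trials_df = None
    else:
        trials_df, metadata = simulate_cohort(config.simulation.to_simulation_config(), grid)
        trials = _frame_to_trials(trials_df, "<simulated>")

    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("rwpt %s | config hash %s | simulation seed %s | statistics seed %s",
                    __version__, _config_hash(config),
                    config.simulation.master_seed, config.statistics.seed)
        if trials_df is not None:
            write_trials(trials, outdir / "trials.csv")
            metadata.to_csv(outdir / "metadata.csv", index=False)

        by_pid: dict[str, list[PointingTrial]] = {}
        for t in trials:
            by_pid.setdefault(t.participant_id, []).append(t)
        amap = config.scoring.to_aggregate_map()
        all_metrics = []
        for pid, ts in by_pid.items():
            m = score_participant(ts, grid, config.scoring.calibration_threshold_deg, amap)
            if m.calibration_excluded:
                logger.info("participant %s excluded: overly inaccurate calibration "
                            "(quality %s)", pid,
                            {k: round(v, 2) for k, v in m.calibration_quality.items()})
            all_metrics.append(m)
        metrics = metrics_to_frame(all_metrics)
        write_metrics(metrics, outdir / "metrics.csv")

        usable = metrics[~metrics["calibration_excluded"]]
        report = run_statistics(usable, metadata, config.statistics.to_plan())
        report["run"] = {"package_version": __version__, "config_hash": _config_hash(config),
                         "simulation_seed": config.simulation.master_seed,
                         "statistics_seed": config.statistics.seed,
                         "n_participants": len(by_pid),
                         "n_excluded": int(metrics.groupby("participant_id")
                                           ["calibration_excluded"].first().sum())}
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        (outdir / "report.md").write_text(report_to_markdown(report))
        logger.info("pipeline complete: %d participants, %d excluded",
                    report["run"]["n_participants"], report["run"]["n_excluded"])
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
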