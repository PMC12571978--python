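"""Turn raw pointing trials into per-participant accuracy, strategy and spread metrics.

A participant performs two calibration paradigms (world-based, with a laser
pointer visualizing the pointing vector, and retinotopic, aligning finger and
target by eye) followed by five eyes-closed test paradigms: initial
reproduction (T1), pointing after a passive 90-degree yaw rotation toward the
non-dominant side (T2), back at the initial orientation (T3), after a rotation
toward the dominant side (T4), and back again (T5).  Each test paradigm is
scored twice, once against each calibration frame, and in each of the two
angular planes (azimuth = horizontal, polar = vertical).

Per paradigm x frame x plane the score is the mean absolute signed angular
deviation over the nine targets (repeats averaged within target first, so
unbalanced repeat counts do not reweight targets) together with the sample
standard deviation of the nine signed deviations ("spread").  Aggregates:

* overall        = mean over T1..T5
* reproduction   = T1
* transformation = mean(T2, T4)   (pointing while rotated: mental transformation)
* postrotation   = mean(T3, T5)   (back at start: tests heading updating)
* strategy index = retinotopic deviation - world deviation, averaged over
  T1..T5 per plane; negative values indicate predominantly retinotopic /
  egocentric spatial encoding
* disorganization = mean spread over T1..T5 per frame x plane

Rotated paradigms are scored against the same room-referenced calibration:
targets are static, so a correct response points at the remembered world
position regardless of body orientation, and any uncompensated heading error
surfaces as azimuth deviation.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    TARGET_LABELS,
    Direction3,
    SphericalAngles,
    TargetGrid,
    angular_diff,
    circular_mean_deg,
    from_spherical,
    target_true_angles,
    to_spherical,
)

__all__ = [
    "ParadigmID",
    "TEST_PARADIGMS",
    "CALIBRATION_PARADIGMS",
    "FRAMES",
    "PLANES",
    "AGGREGATES",
    "DEFAULT_AGGREGATE_MAP",
    "PointingTrial",
    "CalibrationSet",
    "DeviationScore",
    "ParticipantMetrics",
    "ScoringError",
    "IncompleteCalibrationError",
    "ExcludedCalibrationError",
    "MissingTargetsError",
    "build_calibration",
    "score_paradigm",
    "aggregate_metrics",
    "score_participant",
    "metrics_to_frame",
]


class ParadigmID(str, enum.Enum):
    """The two calibration and five test paradigms, in task order."""

    CAL_WORLD = "CAL_WORLD"
    CAL_RETINO = "CAL_RETINO"
    T1_INITIAL = "T1_INITIAL"
    T2_ROTATED_ND = "T2_ROTATED_ND"
    T3_BACK_1 = "T3_BACK_1"
    T4_ROTATED_D = "T4_ROTATED_D"
    T5_BACK_2 = "T5_BACK_2"


TEST_PARADIGMS = (
    ParadigmID.T1_INITIAL,
    ParadigmID.T2_ROTATED_ND,
    ParadigmID.T3_BACK_1,
    ParadigmID.T4_ROTATED_D,
    ParadigmID.T5_BACK_2,
)
CALIBRATION_PARADIGMS = (ParadigmID.CAL_WORLD, ParadigmID.CAL_RETINO)
FRAMES = ("retinotopic", "world")
PLANES = ("azimuth", "polar")
AGGREGATES = ("overall", "reproduction", "transformation", "postrotation")

DEFAULT_AGGREGATE_MAP: dict[str, tuple[ParadigmID, ...]] = {
    "reproduction": (ParadigmID.T1_INITIAL,),
    "transformation": (ParadigmID.T2_ROTATED_ND, ParadigmID.T4_ROTATED_D),
    "postrotation": (ParadigmID.T3_BACK_1, ParadigmID.T5_BACK_2),
}

_CAL_MODE = {ParadigmID.CAL_WORLD: "world", ParadigmID.CAL_RETINO: "retinotopic"}


class ScoringError(ValueError):
    pass


class IncompleteCalibrationError(ScoringError):
    pass


class ExcludedCalibrationError(ScoringError):
    pass


class MissingTargetsError(ScoringError):
    pass


@dataclass(frozen=True)
class PointingTrial:
    """One pointing response: who, when, at what, and in which direction."""

    participant_id: str
    paradigm: ParadigmID
    trial_index: int
    target: tuple[str, str]
    direction: Direction3

    def __post_init__(self) -> None:
        if self.target not in TARGET_LABELS:
            raise ScoringError(f"unknown target label {self.target!r}")
        if self.trial_index < 0:
            raise ScoringError("trial_index must be >= 0")

    @property
    def angles(self) -> SphericalAngles:
        return to_spherical(self.direction)


@dataclass(frozen=True)
class CalibrationSet:
    """Per-target reference angles for one encoding frame.

    quality is the mean absolute angular offset of the references from the
    true target angles (great-circle separation per target, averaged over the
    nine targets).  A participant whose calibration quality exceeds the
    configured threshold is excluded from scoring ("overly inaccurate"
    calibration).
    """

    mode: str
    reference: Mapping[tuple[str, str], SphericalAngles]
    quality: float
    excluded: bool


@dataclass(frozen=True)
class DeviationScore:
    paradigm: ParadigmID
    frame: str
    plane: str
    mean_abs_dev: float
    spread: float
    signed_devs: tuple[float, ...] = field(repr=False, default=())


@dataclass
class ParticipantMetrics:
    """Per-participant summary: aggregates per frame x plane, strategy, spread.

    ``aggregates[(frame, plane)]`` maps aggregate name -> degrees;
    ``strategy_index[plane]`` and ``disorganization[(frame, plane)]`` follow
    the conventions in the module docstring.  When ``calibration_excluded``
    is set, the dictionaries are empty.
    """

    participant_id: str
    aggregates: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    strategy_index: dict[str, float] = field(default_factory=dict)
    disorganization: dict[tuple[str, str], float] = field(default_factory=dict)
    calibration_excluded: bool = False
    calibration_quality: dict[str, float] = field(default_factory=dict)


def _group_by_target(trials: Iterable[PointingTrial]) -> dict[tuple[str, str], list[PointingTrial]]:
    by_target: dict[tuple[str, str], list[PointingTrial]] = {}
    for t in trials:
        by_target.setdefault(t.target, []).append(t)
    return by_target


def _mean_angles(trials: Sequence[PointingTrial]) -> SphericalAngles:
    """Average repeated responses at one target: circular mean azimuth, arithmetic mean polar."""
    az = circular_mean_deg([t.angles.azimuth for t in trials])
    pol = float(np.mean([t.angles.polar for t in trials]))
    return SphericalAngles(az, pol)


def build_calibration(
    trials: Sequence[PointingTrial],
    mode: str,
    grid: TargetGrid,
    exclusion_threshold: float = 10.0,
) -> CalibrationSet:
    """Build the per-target reference angles for one calibration paradigm.

    All trials must belong to the calibration paradigm matching ``mode`` and
    every one of the nine targets must appear at least once.
    """
    if mode not in FRAMES:
        raise ScoringError(f"mode must be one of {FRAMES}, got {mode!r}")
    expected = ParadigmID.CAL_WORLD if mode == "world" else ParadigmID.CAL_RETINO
    wrong = {t.paradigm for t in trials} - {expected}
    if wrong:
        raise ScoringError(f"calibration mode {mode!r} but trials from {sorted(p.value for p in wrong)}")
    by_target = _group_by_target(trials)
    missing = [lbl for lbl in TARGET_LABELS if lbl not in by_target]
    if missing:
        raise IncompleteCalibrationError(f"calibration missing targets: {missing}")

    reference = {lbl: _mean_angles(by_target[lbl]) for lbl in TARGET_LABELS}
    offsets = []
    for lbl in TARGET_LABELS:
        u = from_spherical(reference[lbl]).as_array()
        v = from_spherical(target_true_angles(grid, lbl)).as_array()
        # chord form: numerically stable for near-identical directions
        offsets.append(np.degrees(2.0 * np.arcsin(
            np.clip(np.linalg.norm(u - v) / 2.0, 0.0, 1.0))))
    quality = float(np.mean(offsets))
    return CalibrationSet(mode=mode, reference=reference, quality=quality,
                          excluded=quality > exclusion_threshold)


def score_paradigm(
    trials: Sequence[PointingTrial],
    calibration: CalibrationSet,
) -> dict[str, DeviationScore]:
    """Score one test paradigm against one calibration; returns one score per plane."""
    if calibration.excluded:
        raise ExcludedCalibrationError(
            f"refusing to score against excluded {calibration.mode} calibration "
            f"(quality {calibration.quality:.2f} deg)")
    paradigms = {t.paradigm for t in trials}
    if len(paradigms) != 1:
        raise ScoringError(f"trials span paradigms {sorted(p.value for p in paradigms)}; expected one")
    paradigm = paradigms.pop()
    if paradigm not in TEST_PARADIGMS:
        raise ScoringError(f"{paradigm.value} is not a test paradigm")
    by_target = _group_by_target(trials)
    missing = [lbl for lbl in TARGET_LABELS if lbl not in by_target]
    if missing:
        raise MissingTargetsError(f"paradigm {paradigm.value} missing targets: {missing}")

    devs = {"azimuth": [], "polar": []}
    for lbl in TARGET_LABELS:
        measured = _mean_angles(by_target[lbl])
        ref = calibration.reference[lbl]
        devs["azimuth"].append(angular_diff(measured.azimuth, ref.azimuth))
        devs["polar"].append(angular_diff(measured.polar, ref.polar))

    out = {}
    for plane, d in devs.items():
        out[plane] = DeviationScore(
            paradigm=paradigm,
            frame=calibration.mode,
            plane=plane,
            mean_abs_dev=float(np.mean(np.abs(d))),
            spread=float(statistics.stdev(d)),  # n-1 denominator over the 9 signed deviations
            signed_devs=tuple(d),
        )
    return out


def aggregate_metrics(
    participant_id: str,
    scores: Mapping[tuple[ParadigmID, str], Mapping[str, DeviationScore]],
    aggregate_map: Mapping[str, Sequence[ParadigmID]] | None = None,
) -> ParticipantMetrics:
    """Collapse the 5 paradigms x 2 frames x 2 planes score set into ParticipantMetrics.

    ``scores`` is keyed by (paradigm, frame) and maps plane -> DeviationScore.
    """
    amap = dict(DEFAULT_AGGREGATE_MAP if aggregate_map is None else aggregate_map)
    missing = [(p.value, f) for p in TEST_PARADIGMS for f in FRAMES if (p, f) not in scores]
    if missing:
        raise ScoringError(f"incomplete score set; missing {missing}")

    metrics = ParticipantMetrics(participant_id=participant_id)
    for frame in FRAMES:
        for plane in PLANES:
            per_paradigm = {p: scores[(p, frame)][plane].mean_abs_dev for p in TEST_PARADIGMS}
            agg = {"overall": float(np.mean([per_paradigm[p] for p in TEST_PARADIGMS]))}
            for name, paradigms in amap.items():
                agg[name] = float(np.mean([per_paradigm[p] for p in paradigms]))
            metrics.aggregates[(frame, plane)] = agg
            metrics.disorganization[(frame, plane)] = float(
                np.mean([scores[(p, frame)][plane].spread for p in TEST_PARADIGMS]))
    for plane in PLANES:
        metrics.strategy_index[plane] = float(np.mean([
            scores[(p, "retinotopic")][plane].mean_abs_dev - scores[(p, "world")][plane].mean_abs_dev
            for p in TEST_PARADIGMS]))
    return metrics


def score_participant(
    trials: Sequence[PointingTrial],
    grid: TargetGrid,
    exclusion_threshold: float = 10.0,
    aggregate_map: Mapping[str, Sequence[ParadigmID]] | None = None,
) -> ParticipantMetrics:
    """Full per-participant scoring: calibrations, paradigm scores, aggregates.

    Returns a metrics record flagged ``calibration_excluded`` (with empty
    metric dictionaries) when either calibration exceeds the quality
    threshold; structural problems (missing paradigms/targets) raise with the
    participant id in the message.
    """
    pids = {t.participant_id for t in trials}
    if len(pids) != 1:
        raise ScoringError(f"trials span participants {sorted(pids)}; expected one")
    pid = pids.pop()
    by_paradigm: dict[ParadigmID, list[PointingTrial]] = {}
    for t in trials:
        by_paradigm.setdefault(t.paradigm, []).append(t)
    missing = [p.value for p in (*CALIBRATION_PARADIGMS, *TEST_PARADIGMS) if p not in by_paradigm]
    if missing:
        raise ScoringError(f"participant {pid}: missing paradigms {missing}")

    try:
        calibrations = {
            _CAL_MODE[p]: build_calibration(by_paradigm[p], _CAL_MODE[p], grid, exclusion_threshold)
            for p in CALIBRATION_PARADIGMS
        }
    except ScoringError as e:
        raise type(e)(f"participant {pid}: {e}") from e

    quality = {mode: cal.quality for mode, cal in calibrations.items()}
    if any(cal.excluded for cal in calibrations.values()):
        return ParticipantMetrics(participant_id=pid, calibration_excluded=True,
                                  calibration_quality=quality)

    scores: dict[tuple[ParadigmID, str], dict[str, DeviationScore]] = {}
    for p in TEST_PARADIGMS:
        for frame in FRAMES:
            try:
                scores[(p, frame)] = score_paradigm(by_paradigm[p], calibrations[frame])
            except ScoringError as e:
                raise type(e)(f"participant {pid}: {e}") from e
    metrics = aggregate_metrics(pid, scores, aggregate_map)
    metrics.calibration_quality = quality
    return metrics


def metrics_to_frame(metrics: Iterable[ParticipantMetrics]) -> pd.DataFrame:
    """Tidy table: one row per participant x frame x plane.

    Columns: the four aggregates (degrees), disorganization, the per-plane
    strategy index (repeated across frames, being a frame difference), and
    the calibration-exclusion flag.  Excluded participants contribute rows
    with NaN metrics so exclusions stay visible downstream.
    """
    rows = []
    for m in metrics:
        for frame in FRAMES:
            for plane in PLANES:
                row = {"participant_id": m.participant_id, "frame": frame, "plane": plane,
                       "calibration_excluded": m.calibration_excluded}
                if m.calibration_excluded:
                    row.update({f"{a}_dev": np.nan for a in AGGREGATES})
                    row.update({"disorganization": np.nan, "strategy_index": np.nan})
                else:
                    agg = m.aggregates[(frame, plane)]
                    row.update({f"{a}_dev": agg[a] for a in AGGREGATES})
                    row["disorganization"] = m.disorganization[(frame, plane)]
                    row["strategy_index"] = m.strategy_index[plane]
                rows.append(row)
    return pd.DataFrame(rows)
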