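"""Generative model for synthetic pointing-task cohorts (healthy controls, BVP, PPPD).

The generator produces raw trial logs in exactly the dialect the scoring
pipeline consumes, plus a participant-metadata table, so the full analysis
runs without any external data.  The per-participant model is deliberately
minimal but captures the three mechanisms that separate the clinical groups:

* **Motor execution noise** — each pointing response receives independent
  Gaussian noise per plane (``sigma_motor_az``, ``sigma_motor_pol``).
* **Vestibular heading error** — each passive 90-degree whole-body yaw
  rotation (before T2, T3, T4, T5; first rotation toward the non-dominant
  side, signs mirrored for left-handers) is tracked imperfectly.  Event k
  contributes ``eps_k ~ N((1 - vest_gain) * 90 * sign_k, sigma_vest)``, and
  the accumulated heading error follows ``H <- (1 - rho) * H + eps_k`` with
  H = 0 before T1.  ``rho`` models partial re-anchoring at each
  return-to-start; ``vest_gain`` < 1 models peripheral under-perception of
  rotation (bilateral vestibulopathy).  Heading error is purely horizontal,
  so it contaminates azimuth deviations only — the polar plane stays clean,
  mirroring the empirical azimuth-specific group differences.
* **Reference-frame weighting** — the intended direction is the convex
  combination ``w * retinotopic_reference + (1 - w) * world_reference`` in
  angle space (angles here are small, so no wrap handling is needed).
  With a nonzero retinotopic-vs-world calibration offset (``retino_bias``),
  w = 1 makes the retinotopic calibration fit better (negative strategy
  index, egocentric encoding) and w = 0 the world-based one.

Group presets are demonstration defaults chosen to reproduce the qualitative
group-by-paradigm structure (BVP > PPPD > HC in post-rotation azimuth
deviation); validation of the generator is parameter recovery against the
closed-form half-normal expectations, never matching clinical means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import SphericalAngles, TargetGrid, circular_mean_deg, from_spherical, target_true_angles
from .scoring import (
    CALIBRATION_PARADIGMS,
    TARGET_LABELS,
    TEST_PARADIGMS,
    ParadigmID,
    PointingTrial,
)

__all__ = [
    "ParticipantModel",
    "GroupPreset",
    "SimulationConfig",
    "DEFAULT_GROUP_PRESETS",
    "simulate_participant",
    "simulate_cohort",
    "trials_to_frame",
]


@dataclass(frozen=True)
class ParticipantModel:
    """Generative parameters for one participant (all angles in degrees)."""

    group: str = "HC"
    sigma_motor_az: float = 5.0
    sigma_motor_pol: float = 5.0
    vest_gain: float = 1.0          # perceived / actual rotation ratio
    sigma_vest: float = 2.0         # per-rotation-event tracking noise
    frame_weight: float = 0.5       # 1 = fully retinotopic, 0 = fully world-based
    retino_bias_az: float = 2.0     # systematic retinotopic-vs-world calibration offset
    retino_bias_pol: float = 1.0
    sigma_cal: float = 2.0          # per-trial calibration noise
    heading_reset: float = 0.5      # rho: fraction of heading error shed per paradigm change
    handedness: str = "right"

    def __post_init__(self) -> None:
        for name in ("sigma_motor_az", "sigma_motor_pol", "sigma_vest", "sigma_cal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.frame_weight <= 1.0):
            raise ValueError("frame_weight must lie in [0, 1]")
        if not (0.0 <= self.heading_reset <= 1.0):
            raise ValueError("heading_reset must lie in [0, 1]")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")


@dataclass(frozen=True)
class GroupPreset:
    """Between-subject distribution of ParticipantModel parameters for one group.

    Each participant draws parameters from independent normals
    (mean from ``model``, SD from ``between_sd``), clipped to the valid range.
    Questionnaire placeholders are drawn from truncated normals with the
    instrument-range bounds given in SimulationConfig.
    """

    model: ParticipantModel
    between_sd: Mapping[str, float] = field(default_factory=dict)
    age_mean: float = 45.0
    age_sd: float = 12.0
    prop_female: float = 0.5
    questionnaires: Mapping[str, tuple[float, float]] = field(default_factory=dict)


_PARAM_BOUNDS = {
    "sigma_motor_az": (0.0, None), "sigma_motor_pol": (0.0, None),
    "vest_gain": (0.0, None), "sigma_vest": (0.0, None),
    "frame_weight": (0.0, 1.0), "retino_bias_az": (None, None),
    "retino_bias_pol": (None, None), "sigma_cal": (0.0, None),
    "heading_reset": (0.0, 1.0),
}

#: score bounds per questionnaire instrument (truncation limits for placeholders)
QUESTIONNAIRE_RANGES = {
    "moca": (0.0, 30.0), "phq9": (0.0, 27.0), "sbsods": (1.0, 7.0),
    "eisod_overall": (1.0, 5.0), "eisod_mental_imagery": (1.0, 5.0),
    "eisod_scalar": (1.0, 5.0), "eisod_manipulation": (1.0, 5.0),
    "eisod_navigation": (1.0, 5.0), "stai_state": (20.0, 80.0), "stai_trait": (20.0, 80.0),
}

_DEFAULT_BETWEEN_SD = {
    "sigma_motor_az": 1.0, "sigma_motor_pol": 1.0, "vest_gain": 0.03,
    "sigma_vest": 1.0, "frame_weight": 0.15, "retino_bias_az": 1.0,
    "retino_bias_pol": 0.5, "sigma_cal": 0.5, "heading_reset": 0.1,
}

# Questionnaire (mean, sd) placeholders follow the published cohort descriptives.
DEFAULT_GROUP_PRESETS: dict[str, GroupPreset] = {
    "HC": GroupPreset(
        model=ParticipantModel(group="HC", sigma_motor_az=5.0, sigma_motor_pol=5.0,
                               vest_gain=1.0, sigma_vest=2.0),
        between_sd=_DEFAULT_BETWEEN_SD,
        age_mean=44.78, age_sd=14.40, prop_female=15 / 32,
        questionnaires={"moca": (28.40, 1.43), "phq9": (3.40, 3.60), "sbsods": (4.58, 1.12),
                        "eisod_overall": (3.81, 0.62), "eisod_mental_imagery": (3.88, 0.65),
                        "eisod_scalar": (4.07, 0.87), "eisod_manipulation": (3.45, 0.94),
                        "eisod_navigation": (3.84, 0.84),
                        "stai_state": (27.04, 16.39), "stai_trait": (31.22, 9.46)},
    ),
    "BVP": GroupPreset(
        model=ParticipantModel(group="BVP", sigma_motor_az=5.5, sigma_motor_pol=5.5,
                               vest_gain=0.9, sigma_vest=8.0),
        between_sd=_DEFAULT_BETWEEN_SD,
        age_mean=52.44, age_sd=12.00, prop_female=17 / 32,
        questionnaires={"moca": (28.31, 1.34), "phq9": (4.61, 3.28), "sbsods": (4.69, 0.98),
                        "eisod_overall": (3.39, 0.95), "eisod_mental_imagery": (3.69, 0.84),
                        "eisod_scalar": (3.19, 1.17), "eisod_manipulation": (2.96, 1.24),
                        "eisod_navigation": (3.71, 1.14),
                        "stai_state": (34.62, 17.31), "stai_trait": (27.47, 12.37)},
    ),
    "PPPD": GroupPreset(
        model=ParticipantModel(group="PPPD", sigma_motor_az=5.5, sigma_motor_pol=5.5,
                               vest_gain=0.97, sigma_vest=5.0),
        between_sd=_DEFAULT_BETWEEN_SD,
        age_mean=45.93, age_sd=11.72, prop_female=25 / 43,
        questionnaires={"moca": (28.35, 1.55), "phq9": (7.79, 5.82), "sbsods": (4.76, 0.99),
                        "eisod_overall": (3.53, 0.84), "eisod_mental_imagery": (3.69, 1.06),
                        "eisod_scalar": (3.59, 1.20), "eisod_manipulation": (3.34, 0.86),
                        "eisod_navigation": (3.51, 1.07),
                        "stai_state": (42.81, 17.79), "stai_trait": (40.25, 17.68)},
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings; the master seed fully determines output."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"BVP": 32, "PPPD": 43, "HC": 32})
    presets: Mapping[str, GroupPreset] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PRESETS))
    repeats: int = 1
    master_seed: int = 0
    age_bounds: tuple[float, float] = (18.0, 65.0)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = set(self.group_sizes) - set(self.presets)
        if unknown:
            raise ValueError(f"no preset for groups {sorted(unknown)}")


# Rotation events occur before T2..T5; first rotation toward the non-dominant
# side.  Nominal signed magnitudes for right-handers, mirrored for left-handers.
_NOMINAL_SIGNS = (-1.0, +1.0, +1.0, -1.0)
_ROTATED_PARADIGMS = TEST_PARADIGMS[1:]  # T2..T5


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Draw by resampling; falls back to clipping after 100 rejections."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def simulate_participant(
    model: ParticipantModel,
    grid: TargetGrid,
    seed,
    participant_id: str = "sim",
    repeats: int = 1,
) -> list[PointingTrial]:
    """Generate the full trial log (2 calibration + 5 test paradigms) for one participant.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the same seed
    always reproduces the identical trial list.
    """
    rng = np.random.default_rng(seed)
    true = {lbl: target_true_angles(grid, lbl) for lbl in TARGET_LABELS}

    trials: list[PointingTrial] = []
    cal_trials: dict[str, dict[tuple[str, str], list[SphericalAngles]]] = {
        "world": {}, "retinotopic": {}}
    idx = 0
    for paradigm, mode, bias_az, bias_pol in (
            (ParadigmID.CAL_WORLD, "world", 0.0, 0.0),
            (ParadigmID.CAL_RETINO, "retinotopic", model.retino_bias_az, model.retino_bias_pol)):
        for lbl in TARGET_LABELS:
            for _ in range(repeats):
                az = true[lbl].azimuth + bias_az + rng.normal(0.0, model.sigma_cal)
                pol = np.clip(true[lbl].polar + bias_pol + rng.normal(0.0, model.sigma_cal), -90, 90)
                ang = SphericalAngles(_wrap(az), float(pol))
                cal_trials[mode].setdefault(lbl, []).append(ang)
                trials.append(PointingTrial(participant_id, paradigm, idx, lbl, from_spherical(ang)))
                idx += 1

    # The participant's own references are what the calibration paradigms
    # established: circular-mean azimuth, arithmetic-mean polar per target.
    refs = {}
    for mode, per_target in cal_trials.items():
        refs[mode] = {
            lbl: (circular_mean_deg([a.azimuth for a in angs]),
                  float(np.mean([a.polar for a in angs])))
            for lbl, angs in per_target.items()}

    mirror = -1.0 if model.handedness == "left" else 1.0
    heading = {ParadigmID.T1_INITIAL: 0.0}
    h = 0.0
    for paradigm, sign in zip(_ROTATED_PARADIGMS, _NOMINAL_SIGNS):
        s = sign * mirror
        eps = rng.normal((1.0 - model.vest_gain) * 90.0 * s, model.sigma_vest)
        h = (1.0 - model.heading_reset) * h + eps
        heading[paradigm] = h

    w = model.frame_weight
    for paradigm in TEST_PARADIGMS:
        for lbl in TARGET_LABELS:
            r_az, r_pol = refs["retinotopic"][lbl]
            w_az, w_pol = refs["world"][lbl]
            intended_az = w * r_az + (1.0 - w) * w_az + heading[paradigm]
            intended_pol = w * r_pol + (1.0 - w) * w_pol
            for _ in range(repeats):
                az = _wrap(intended_az + rng.normal(0.0, model.sigma_motor_az))
                pol = float(np.clip(intended_pol + rng.normal(0.0, model.sigma_motor_pol), -90, 90))
                trials.append(PointingTrial(
                    participant_id, paradigm, idx, lbl,
                    from_spherical(SphericalAngles(az, pol))))
                idx += 1
    return trials


def _wrap(a: float) -> float:
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    if a <= -180.0:
        a += 360.0
    return a


def _draw_model(preset: GroupPreset, rng: np.random.Generator) -> ParticipantModel:
    kwargs = {}
    for name, (lo, hi) in _PARAM_BOUNDS.items():
        mean = getattr(preset.model, name)
        sd = preset.between_sd.get(name, 0.0)
        x = rng.normal(mean, sd) if sd > 0 else mean
        kwargs[name] = float(np.clip(x, lo if lo is not None else -np.inf,
                                     hi if hi is not None else np.inf))
    handedness = "left" if rng.random() < 0.10 else "right"
    return replace(preset.model, handedness=handedness, **kwargs)


def simulate_cohort(
    config: SimulationConfig,
    grid: TargetGrid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials table, metadata table).

    Per-participant random substreams are spawned from the master seed keyed
    by cohort index, so editing one group's size never perturbs the draws of
    participants that come before it in the roster.
    """
    grid = grid or TargetGrid()
    all_trials: list[PointingTrial] = []
    meta_rows = []
    index = 0
    for group in config.group_sizes:
        preset = config.presets[group]
        for _ in range(config.group_sizes[group]):
            pid = f"{group}{index:03d}"
            param_seq, trial_seq, meta_seq = (
                np.random.SeedSequence(entropy=config.master_seed, spawn_key=(index, k))
                for k in range(3))
            model = _draw_model(preset, np.random.default_rng(param_seq))
            all_trials.extend(simulate_participant(model, grid, trial_seq, pid, config.repeats))

            mrng = np.random.default_rng(meta_seq)
            row = {
                "participant_id": pid,
                "group": group,
                "age": _truncated_normal(mrng, preset.age_mean, preset.age_sd, *config.age_bounds),
                "sex": "F" if mrng.random() < preset.prop_female else "M",
                "handedness": model.handedness,
            }
            for name, (mean, sd) in preset.questionnaires.items():
                lo, hi = QUESTIONNAIRE_RANGES.get(name, (-np.inf, np.inf))
                row[name] = _truncated_normal(mrng, mean, sd, lo, hi)
            # clinical flags / disease duration: patients only
            if group == "HC":
                row.update(avoidance_behavior=False, visual_aggravation=False,
                           functional_sway=False, disease_duration_months=np.nan)
            else:
                row.update(
                    avoidance_behavior=bool(mrng.random() < 0.5),
                    visual_aggravation=bool(mrng.random() < (0.7 if group == "PPPD" else 0.3)),
                    functional_sway=bool(group == "PPPD" and mrng.random() < 14 / 33),
                    disease_duration_months=float(np.round(
                        _truncated_normal(mrng, 29.0, 41.0, 1.0, 200.0), 1)))
            meta_rows.append(row)
            index += 1
    return trials_to_frame(all_trials), pd.DataFrame(meta_rows)


def trials_to_frame(trials: list[PointingTrial]) -> pd.DataFrame:
    """Serialize trials to the canonical CSV dialect (unit-vector representation)."""
    return pd.DataFrame([
        {"participant_id": t.participant_id, "paradigm": t.paradigm.value,
         "trial_index": t.trial_index, "target_row": t.target[0], "target_col": t.target[1],
         "dir_x": t.direction.x, "dir_y": t.direction.y, "dir_z": t.direction.z}
        for t in trials])
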