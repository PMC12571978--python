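"""Scoring-pipeline tests, including the explicit-loop brute-force oracle."""

import math
import statistics

import numpy as np
import pytest

from rwpt.geometry import (
    TARGET_LABELS,
    SphericalAngles,
    TargetGrid,
    angular_diff,
    from_spherical,
    target_true_angles,
    to_spherical,
)
from rwpt.scoring import (
    FRAMES,
    PLANES,
    TEST_PARADIGMS,
    ExcludedCalibrationError,
    IncompleteCalibrationError,
    MissingTargetsError,
    ParadigmID,
    PointingTrial,
    ScoringError,
    aggregate_metrics,
    build_calibration,
    metrics_to_frame,
    score_paradigm,
    score_participant,
)

from conftest import make_trials


# --- independent brute-force oracle: explicit loops, no pipeline reuse ------

def brute_circ_mean(angles):
    s = sum(math.sin(math.radians(a)) for a in angles)
    c = sum(math.cos(math.radians(a)) for a in angles)
    return math.degrees(math.atan2(s, c))


def brute_wrap(d):
    while d <= -180:
        d += 360
    while d > 180:
        d -= 360
    return d


def brute_score(trials, reference):
    """Per-plane (mean_abs_dev, spread) recomputed with plain loops."""
    per_target = {}
    for t in trials:
        per_target.setdefault(t.target, []).append(t)
    devs = {"azimuth": [], "polar": []}
    for lbl, ts in sorted(per_target.items()):
        az = brute_circ_mean([to_spherical(t.direction).azimuth for t in ts])
        pol = sum(to_spherical(t.direction).polar for t in ts) / len(ts)
        devs["azimuth"].append(brute_wrap(az - reference[lbl][0]))
        devs["polar"].append(brute_wrap(pol - reference[lbl][1]))
    out = {}
    for plane in devs:
        d = devs[plane]
        mean_abs = sum(abs(x) for x in d) / len(d)
        mean = sum(d) / len(d)
        spread = math.sqrt(sum((x - mean) ** 2 for x in d) / (len(d) - 1))
        out[plane] = (mean_abs, spread)
    return out


def random_paradigm_trials(rng, paradigm=ParadigmID.T1_INITIAL, max_repeats=3):
    trials = []
    idx = 0
    for lbl in TARGET_LABELS:
        for _ in range(int(rng.integers(1, max_repeats + 1))):
            az = float(rng.uniform(-179.9, 180))
            pol = float(rng.uniform(-89, 89))
            trials.append(PointingTrial("p", paradigm, idx, lbl,
                                        from_spherical(SphericalAngles(az, pol))))
            idx += 1
    return trials


# --- calibration -----------------------------------------------------------

class TestBuildCalibration:
    def test_reference_is_mean_of_repeats(self, grid):
        trials = []
        for i, az in enumerate((10.0, 20.0)):
            for lbl in TARGET_LABELS:
                true = target_true_angles(grid, lbl)
                trials.append(PointingTrial("p", ParadigmID.CAL_WORLD, i, lbl,
                                            from_spherical(SphericalAngles(az, true.polar))))
        cal = build_calibration(trials, "world", grid, exclusion_threshold=90.0)
        for lbl in TARGET_LABELS:
            assert cal.reference[lbl].azimuth == pytest.approx(15.0, abs=1e-9)

    def test_circular_mean_across_wrap(self, grid):
        trials = []
        for i, az in enumerate((179.0, -179.0)):
            for lbl in TARGET_LABELS:
                trials.append(PointingTrial("p", ParadigmID.CAL_WORLD, i, lbl,
                                            from_spherical(SphericalAngles(az, 0.0))))
        cal = build_calibration(trials, "world", grid, exclusion_threshold=360.0)
        assert cal.reference[("center", "center")].azimuth == pytest.approx(180.0, abs=1e-9)

    def test_perfect_calibration_quality_zero(self, grid):
        trials = [t for t in make_trials(grid) if t.paradigm is ParadigmID.CAL_WORLD]
        cal = build_calibration(trials, "world", grid)
        assert cal.quality == pytest.approx(0.0, abs=1e-9)
        assert not cal.excluded

    def test_exclusion_threshold(self, grid):
        trials = []
        for lbl in TARGET_LABELS:
            true = target_true_angles(grid, lbl)
            trials.append(PointingTrial("p", ParadigmID.CAL_WORLD, 0, lbl,
                                        from_spherical(SphericalAngles(true.azimuth + 25, true.polar))))
        cal = build_calibration(trials, "world", grid, exclusion_threshold=10.0)
        # 25 deg azimuth offset: great-circle separation is 25 deg on the
        # center row, slightly less off-center (foreshortened by elevation)
        assert cal.excluded
        assert 24.0 < cal.quality <= 25.0

    def test_missing_target_and_wrong_paradigm(self, grid):
        trials = [t for t in make_trials(grid)
                  if t.paradigm is ParadigmID.CAL_WORLD and t.target != ("top", "left")]
        with pytest.raises(IncompleteCalibrationError):
            build_calibration(trials, "world", grid)
        test_trials = [t for t in make_trials(grid) if t.paradigm is ParadigmID.T1_INITIAL]
        with pytest.raises(ScoringError):
            build_calibration(test_trials, "world", grid)


# --- paradigm scoring ------------------------------------------------------

class TestScoreParadigm:
    def test_constant_offset(self, grid):
        trials = make_trials(grid, offsets={ParadigmID.T1_INITIAL: (5.0, 0.0)})
        cal = build_calibration([t for t in trials if t.paradigm is ParadigmID.CAL_WORLD],
                                "world", grid)
        scores = score_paradigm([t for t in trials if t.paradigm is ParadigmID.T1_INITIAL], cal)
        assert scores["azimuth"].mean_abs_dev == pytest.approx(5.0, abs=1e-9)
        assert scores["azimuth"].spread == pytest.approx(0.0, abs=1e-9)
        assert scores["polar"].mean_abs_dev == pytest.approx(0.0, abs=1e-9)

    def test_alternating_signed_deviations(self):
        devs = [+3, -3, +3, -3, +3, -3, +3, -3, +3]
        assert np.mean(np.abs(devs)) == pytest.approx(3.0)
        expected_spread = statistics.stdev(devs)
        # pipeline on a log engineered to produce those signed deviations
        grid = TargetGrid()
        trials, cal_trials = [], []
        for i, lbl in enumerate(TARGET_LABELS):
            true = target_true_angles(grid, lbl)
            cal_trials.append(PointingTrial("p", ParadigmID.CAL_WORLD, i, lbl,
                                            from_spherical(true)))
            trials.append(PointingTrial("p", ParadigmID.T1_INITIAL, i, lbl,
                                        from_spherical(SphericalAngles(true.azimuth + devs[i],
                                                                       true.polar))))
        cal = build_calibration(cal_trials, "world", grid)
        scores = score_paradigm(trials, cal)
        assert scores["azimuth"].mean_abs_dev == pytest.approx(3.0, abs=1e-9)
        assert scores["azimuth"].spread == pytest.approx(expected_spread, abs=1e-9)

    def test_zero_floor_when_measured_equals_reference(self, grid):
        trials = make_trials(grid)
        cal = build_calibration([t for t in trials if t.paradigm is ParadigmID.CAL_WORLD],
                                "world", grid)
        scores = score_paradigm([t for t in trials if t.paradigm is ParadigmID.T1_INITIAL], cal)
        for plane in PLANES:
            assert scores[plane].mean_abs_dev == pytest.approx(0.0, abs=1e-9)

    def test_refuses_excluded_calibration_and_missing_targets(self, grid):
        trials = make_trials(grid)
        cal = build_calibration([t for t in trials if t.paradigm is ParadigmID.CAL_WORLD],
                                "world", grid)
        bad_cal = type(cal)(mode=cal.mode, reference=cal.reference, quality=20.0, excluded=True)
        t1 = [t for t in trials if t.paradigm is ParadigmID.T1_INITIAL]
        with pytest.raises(ExcludedCalibrationError):
            score_paradigm(t1, bad_cal)
        with pytest.raises(MissingTargetsError, match="top"):
            score_paradigm([t for t in t1 if t.target != ("top", "left")], cal)

    def test_oracle_equivalence_random_instances(self, grid, rng):
        cal_trials = [t for t in make_trials(grid) if t.paradigm is ParadigmID.CAL_WORLD]
        cal = build_calibration(cal_trials, "world", grid)
        ref = {lbl: (cal.reference[lbl].azimuth, cal.reference[lbl].polar)
               for lbl in TARGET_LABELS}
        for _ in range(200):
            trials = random_paradigm_trials(rng)
            scores = score_paradigm(trials, cal)
            expected = brute_score(trials, ref)
            for plane in PLANES:
                assert scores[plane].mean_abs_dev == pytest.approx(expected[plane][0], abs=1e-9)
                assert scores[plane].spread == pytest.approx(expected[plane][1], abs=1e-9)

    def test_rotation_invariance_of_room_frame_scoring(self, grid, rng):
        """Rigid yaw rotation of measured and reference vectors leaves scores unchanged."""
        trials = random_paradigm_trials(rng, max_repeats=1)
        cal_trials = [t for t in make_trials(grid) if t.paradigm is ParadigmID.CAL_WORLD]
        cal = build_calibration(cal_trials, "world", grid, exclusion_threshold=360.0)
        base = score_paradigm(trials, cal)

        def yaw(t, delta):
            s = to_spherical(t.direction)
            az = angular_diff(s.azimuth + delta, 0.0)
            return PointingTrial(t.participant_id, t.paradigm, t.trial_index, t.target,
                                 from_spherical(SphericalAngles(az, s.polar)))

        delta = 37.5
        rot_cal = build_calibration([yaw(t, delta) for t in cal_trials], "world", grid,
                                    exclusion_threshold=360.0)
        rot = score_paradigm([yaw(t, delta) for t in trials], rot_cal)
        for plane in PLANES:
            assert rot[plane].mean_abs_dev == pytest.approx(base[plane].mean_abs_dev, abs=1e-9)
            assert rot[plane].spread == pytest.approx(base[plane].spread, abs=1e-9)


# --- aggregates and the full participant ----------------------------------

class TestAggregatesAndParticipant:
    def test_aggregate_arithmetic(self, grid):
        per_paradigm = dict(zip(TEST_PARADIGMS, [(4, 0), (6, 0), (8, 0), (6, 0), (8, 0)]))
        offsets = {p: (az, 0.0) for p, (az, _) in per_paradigm.items()}
        trials = make_trials(grid, offsets=offsets)
        m = score_participant(trials, grid)
        agg = m.aggregates[("world", "azimuth")]
        assert agg["overall"] == pytest.approx(6.4, abs=1e-9)
        assert agg["reproduction"] == pytest.approx(4.0, abs=1e-9)
        assert agg["transformation"] == pytest.approx(6.0, abs=1e-9)
        assert agg["postrotation"] == pytest.approx(8.0, abs=1e-9)

    def test_strategy_index_sign_convention(self, grid):
        # responses follow the retinotopic frame (offset 3 from world):
        # retinotopic deviation 0, world deviation 3 -> index -3 (egocentric)
        offsets = {p: (3.0, 0.0) for p in TEST_PARADIGMS}
        trials = make_trials(grid, offsets=offsets, retino_offset=(3.0, 0.0))
        m = score_participant(trials, grid)
        assert m.strategy_index["azimuth"] == pytest.approx(-3.0, abs=1e-9)

    def test_strategy_zero_when_frames_coincide(self, grid):
        m = score_participant(make_trials(grid), grid)
        assert m.strategy_index["azimuth"] == pytest.approx(0.0, abs=1e-9)
        assert m.strategy_index["polar"] == pytest.approx(0.0, abs=1e-9)

    def test_strategy_antisymmetry_under_frame_swap(self, grid):
        offsets = {p: (2.0, 0.0) for p in TEST_PARADIGMS}
        trials = make_trials(grid, offsets=offsets, retino_offset=(3.0, 0.0))
        swapped = []
        swap = {ParadigmID.CAL_WORLD: ParadigmID.CAL_RETINO,
                ParadigmID.CAL_RETINO: ParadigmID.CAL_WORLD}
        for t in trials:
            p = swap.get(t.paradigm, t.paradigm)
            swapped.append(PointingTrial(t.participant_id, p, t.trial_index, t.target, t.direction))
        m1 = score_participant(trials, grid)
        m2 = score_participant(swapped, grid)
        for plane in PLANES:
            assert m2.strategy_index[plane] == pytest.approx(-m1.strategy_index[plane], abs=1e-9)

    def test_noise_free_participant_scores_zero(self, grid):
        m = score_participant(make_trials(grid), grid)
        for key, agg in m.aggregates.items():
            for name, value in agg.items():
                assert value == pytest.approx(0.0, abs=1e-9), (key, name)

    def test_inaccurate_world_calibration_excludes(self, grid):
        trials = [t for t in make_trials(grid) if t.paradigm is not ParadigmID.CAL_WORLD]
        for lbl in TARGET_LABELS:
            true = target_true_angles(grid, lbl)
            trials.append(PointingTrial("p1", ParadigmID.CAL_WORLD, 0, lbl,
                                        from_spherical(SphericalAngles(true.azimuth + 20,
                                                                       true.polar))))
        m = score_participant(trials, grid, exclusion_threshold=10.0)
        assert m.calibration_excluded
        assert m.aggregates == {}

    def test_incomplete_scores_and_missing_paradigm(self, grid):
        with pytest.raises(ScoringError):
            aggregate_metrics("p", {})
        trials = [t for t in make_trials(grid) if t.paradigm is not ParadigmID.T5_BACK_2]
        with pytest.raises(ScoringError, match="T5"):
            score_participant(trials, grid)

    def test_participant_equals_manual_composition(self, grid, rng):
        """Full pipeline equals the step-by-step composition of its three stages."""
        from rwpt.scoring import CALIBRATION_PARADIGMS, build_calibration

        offsets = {p: (float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5)))
                   for p in TEST_PARADIGMS}
        trials = make_trials(grid, offsets=offsets, retino_offset=(1.5, -0.5), repeats=2)
        m = score_participant(trials, grid)

        by_paradigm = {}
        for t in trials:
            by_paradigm.setdefault(t.paradigm, []).append(t)
        cals = {"world": build_calibration(by_paradigm[ParadigmID.CAL_WORLD], "world", grid),
                "retinotopic": build_calibration(by_paradigm[ParadigmID.CAL_RETINO],
                                                 "retinotopic", grid)}
        scores = {(p, f): score_paradigm(by_paradigm[p], cals[f])
                  for p in TEST_PARADIGMS for f in FRAMES}
        manual = aggregate_metrics("p1", scores)
        assert manual.aggregates == m.aggregates
        assert manual.strategy_index == m.strategy_index
        assert manual.disorganization == m.disorganization

    def test_metrics_to_frame_shape(self, grid):
        m = score_participant(make_trials(grid), grid)
        df = metrics_to_frame([m])
        assert len(df) == 4  # 2 frames x 2 planes
        assert set(df.columns) >= {"overall_dev", "reproduction_dev", "transformation_dev",
                                   "postrotation_dev", "strategy_index", "disorganization"}
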