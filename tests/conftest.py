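import numpy as np
import pytest

from rwpt.geometry import TARGET_LABELS, SphericalAngles, TargetGrid, from_spherical, target_true_angles
from rwpt.scoring import CALIBRATION_PARADIGMS, TEST_PARADIGMS, ParadigmID, PointingTrial


@pytest.fixture
def grid():
    return TargetGrid()


def make_trials(grid, pid="p1", offsets=None, repeats=1, retino_offset=(0.0, 0.0)):
    """Build a complete synthetic log analytically (no random noise).

    ``offsets`` maps a test ParadigmID to an (azimuth, polar) shift applied to
    every response in that paradigm; calibration trials sit exactly at the
    true target angles (retinotopic ones shifted by ``retino_offset``).
    """
    offsets = offsets or {}
    trials = []
    idx = 0
    for paradigm in (*CALIBRATION_PARADIGMS, *TEST_PARADIGMS):
        if paradigm is ParadigmID.CAL_RETINO:
            d_az, d_pol = retino_offset
        else:
            d_az, d_pol = offsets.get(paradigm, (0.0, 0.0))
        for lbl in TARGET_LABELS:
            true = target_true_angles(grid, lbl)
            ang = SphericalAngles(true.azimuth + d_az, true.polar + d_pol)
            for _ in range(repeats):
                trials.append(PointingTrial(pid, paradigm, idx, lbl, from_spherical(ang)))
                idx += 1
    return trials


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
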