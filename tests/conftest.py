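import numpy as np
import pytest

from gazesweep import ScanProfile, default_room_layout


@pytest.fixture(scope="session")
def layout():
    return default_room_layout()


@pytest.fixture
def quiet_profile():
    """Mid-persistence searcher with no tracking loss, for recovery tests."""
    return ScanProfile(sweep_persistence=0.5, noise_sd=0.1, blink_rate=0.0)


def greedy_f1(gt_onsets, det_onsets, tol=0.025):
    """Event-level F1 with one-to-one onset matching within tol seconds."""
    gt_onsets = np.asarray(gt_onsets)
    used = set()
    tp = 0
    for o in det_onsets:
        d = np.abs(gt_onsets - o)
        j = int(np.argmin(d))
        if d[j] <= tol and j not in used:
            used.add(j)
            tp += 1
    if len(det_onsets) == 0 or len(gt_onsets) == 0:
        return 0.0
    precision = tp / len(det_onsets)
    recall = tp / len(gt_onsets)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
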