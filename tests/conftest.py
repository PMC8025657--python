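import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazechoice.data import GazeSegment, ItemInfo, SubjectDataset, TrialRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trial(
    subject="s00",
    trial=0,
    set_size=9,
    ratings=(-3, -1, 0, 1, 2, 3, 2, 0, -2),
    gaze=((0, 0, 400), (3, 400, 300), (5, 700, 300)),
    choice=5,
    rt=1000,
):
    """Hand-built valid trial; gaze entries are (item, onset, duration)."""
    n = int(np.sqrt(set_size))
    items = [
        ItemInfo(f"i{k:02d}", ratings[k], k // n, k % n, 0.6) for k in range(set_size)
    ]
    segs = [GazeSegment(i, o, d) for i, o, d in gaze]
    return TrialRecord(subject, trial, set_size, items, segs, choice, rt, valid=True)


@pytest.fixture
def trial():
    return make_trial()


def random_dataset(seed, n_subjects=2, n_trials=4, set_size=9):
    """Small random-but-valid dataset for round-trip and property tests."""
    rng = np.random.default_rng(seed)
    n = int(np.sqrt(set_size))
    datasets = []
    for s in range(n_subjects):
        ratings = {f"i{k:02d}": int(rng.integers(-3, 4)) for k in range(20)}
        trials = []
        for t in range(n_trials):
            ids = rng.choice(sorted(ratings), size=set_size, replace=False)
            cells = rng.permutation(set_size)
            items = [
                ItemInfo(i, ratings[i], int(c) // n, int(c) % n, float(rng.uniform(0.3, 1.0)))
                for i, c in zip(ids, cells)
            ]
            segs, pos = [], 0
            for _ in range(int(rng.integers(2, 6))):
                item = int(rng.integers(set_size))
                dur = int(rng.integers(100, 500))
                segs.append(GazeSegment(item, pos, dur))
                pos += dur + int(rng.integers(0, 50))
            rt = pos + int(rng.integers(1, 200))
            choice = segs[int(rng.integers(len(segs)))].item_index
            trials.append(
                TrialRecord(f"s{s:02d}", t, set_size, items, segs, choice, rt, valid=True)
            )
        datasets.append(SubjectDataset(f"s{s:02d}", trials, ratings))
    return datasets


@pytest.fixture
def dataset():
    return random_dataset(0)
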