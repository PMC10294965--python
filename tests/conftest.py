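import numpy as np
import pytest

from primood.schema import PrimitiveClass, Recording, Segment
from primood.synth import SynthConfig, simulate_dataset
from primood.windows import make_windows


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four healthy + two impaired subjects; shared across unit tests."""
    cfg = SynthConfig(n_healthy=4, n_impaired=2, thetas=(0.3, 0.8), seed=11)
    metas, recs, thetas = simulate_dataset(cfg)
    return cfg, metas, recs, thetas


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    _, metas, recs, _ = tiny_cohort
    return {m.subject_id: [w for r in recs[m.subject_id] for w in make_windows(r)]
            for m in metas}


def make_recording(labels_and_lengths, n_channels=76, subject="X", trial="T1",
                   side="right", seed=0):
    """Build a small recording with the given (label, n_frames) segments."""
    rng = np.random.default_rng(seed)
    segments, start = [], 0
    for label, n in labels_and_lengths:
        segments.append(Segment(start, start + n, label))
        start += n
    data = rng.normal(size=(start, n_channels))
    return Recording(subject, trial, side, data, segments)


@pytest.fixture
def idle_recording():
    return make_recording([(PrimitiveClass.IDLE, 700)])
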