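import numpy as np
import pytest

from attnfusion.io_formats import EMOTION_LABELS, EmotionStream, PhysioStream
from attnfusion.physio import CalibrationProfile, SubjectInfo
from attnfusion.synthetic import RegimeSchedule, RegimeSegment, simulate_classroom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def subject_info():
    return SubjectInfo(age=22, gender="f", weight=65, height=172)


@pytest.fixture
def profile():
    return CalibrationProfile(
        subject_id="s01",
        threshold_sdnn=30.0,
        threshold_rmssd=30.0,
        threshold_sdsd=30.0,
        direction="below",
    )


def random_emotion_stream(rng, n, rate_hz=1.0):
    labels = rng.choice(list(EMOTION_LABELS), size=n)
    return EmotionStream(np.arange(n) / rate_hz, labels)


def random_physio_stream(rng, n, mean=800.0, sd=30.0):
    bb = np.maximum(rng.normal(mean, sd, size=n), 100.0)
    return PhysioStream(np.arange(n, dtype=float), 60000.0 / bb, bb)


@pytest.fixture(scope="session")
def two_regime_schedule():
    return RegimeSchedule(
        [RegimeSegment(900, "attentive"), RegimeSegment(900, "distracted")]
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, two_regime_schedule):
    """A compact 3-subject session reused by integration tests."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_classroom(
        3, two_regime_schedule, master_seed=7, out_dir=out, with_prompts=True
    )
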