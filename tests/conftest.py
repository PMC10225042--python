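import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

RATE = 44100.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-class synthetic cohort plus its feature table.

    Session-scoped because featurization dominates test runtime; tests must
    not mutate it.
    """
    import tussilab as tl
    from tussilab.pipeline_cli import RunConfig, featurize_waveforms

    config = RunConfig(seed=7)
    waveforms, cohort = tl.generate_cohort(6, 2, seed=7)
    features = featurize_waveforms(waveforms, config)
    return waveforms, cohort, features, config


def normalized_noise_segment(rng, n=8820, rate=RATE):
    """A seeded white-noise segment normalized to unit average energy."""
    from tussilab.segmentation import Segment
    x = rng.standard_normal(n)
    x /= np.sqrt(np.mean(np.square(x)))
    return Segment(samples=x, rate=rate, onset=0, offset=n)
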