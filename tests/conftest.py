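import numpy as np
import pytest
from hypothesis import settings

import voxstm as vx
from voxstm.pipeline import demo_filterbank_spec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_spec():
    return demo_filterbank_spec()


@pytest.fixture(scope="session")
def strong_effect_features(demo_spec):
    """Small cohort with a strong planted prosody effect, featurised once.

    4 participants x 6 sessions of 60 s, after-deprivation AM depth
    multiplied by 1.5 for everyone.  Shared across classifier and
    interpretation tests to keep the suite fast.
    """
    cfg = vx.CohortConfig(
        n_participants=4,
        session_duration=60.0,
        prosody_effect=0.5,
        prosody_sd=0.0,
        timbre_effect=0.0,
        timbre_sd=0.0,
        seed=3,
    )
    cohort = vx.make_cohort(cfg)
    X, meta = vx.featurize_cohort(cohort, demo_spec)
    return X, meta, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
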