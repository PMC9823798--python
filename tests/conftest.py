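import numpy as np
import pytest

from neoqeeg.synthetic import SimCohortConfig, SubjectSimParams, synthesize_recording

FS = 250.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def short_recording_truth():
    params = SubjectSimParams(subject_id="fix02", baseline_amplitude=80.0,
                              sync_level=0.8, rng_seed=12)
    cfg = SimCohortConfig(duration_pre=600.0, duration_post=600.0)
    return synthesize_recording(params, cfg, return_truth=True)
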