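import numpy as np
import pytest

import rppgeval as rp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free_scene():
    """One 60-s scene with no noise, drift, or artifacts (HR 100 BPM)."""
    spec = rp.SceneSpec(subject_id="S01", activity="Resting", seed=3)
    model = rp.ChannelModel(noise_sd=0.0, drift_amp=0.0, artifact_rate=0.0)
    return rp.generate_scene(spec, model=model,
                             params=rp.BVPParams(hr_bpm=100.0),
                             cppg_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects x four activities at default noise, fixed seed."""
    return rp.generate_cohort(n_subjects=2, master_seed=11)
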