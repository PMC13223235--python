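import numpy as np
import pytest

import feargen as fg


@pytest.fixture(scope="session")
def layout():
    return fg.generate_layout(32, seed=7)


@pytest.fixture(scope="session")
def tuning(layout):
    return fg.design_tuning(layout, seed=7)


@pytest.fixture(scope="session")
def session_noisefree(layout, tuning):
    spec = fg.DrugEffectSpec.conditioned(noise_sd=0.0)
    return fg.generate_session(layout, tuning, spec, seed=7)


@pytest.fixture(scope="session")
def session_noisy(layout, tuning):
    spec = fg.DrugEffectSpec.conditioned(noise_sd=1.0)
    return fg.generate_session(layout, tuning, spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_trial(trace_values, baseline=100.0, odor="MV", phase="pre", mock=False,
               shape=(4, 4)):
    """Build a tiny uniform-field ImagingTrial whose ROI-mean ΔF/F follows
    `trace_values` exactly (frames = baseline * (1 + value))."""
    v = np.asarray(trace_values, dtype=float)
    frames = baseline * (1.0 + v)[:, None, None] * np.ones((1,) + shape)
    return fg.ImagingTrial(frames=frames, odor=odor, phase=phase, mock=mock,
                           segments=(225, 350, 425))
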