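import numpy as np
import pytest

from songlat.simulate import MOTIF_LABELS, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact two-region synthetic session reused across read-only tests."""
    session, ann, wave, gt = simulate_session(
        seed=7,
        n_bouts=12,
        region_configs={
            "HVC": dict(n_clusters=24, p_true=4, trial_variability_scale=0.45,
                        sparse_fraction=0.4),
            "RA": dict(n_clusters=30, p_true=4, trial_variability_scale=0.15),
        },
    )
    return session, ann, wave, gt


@pytest.fixture(scope="session")
def ra_trials(small_session):
    from songlat.preprocess import bin_spikes, segment_trials

    session, ann, _, _ = small_session
    counts = bin_spikes(session, 0.001)
    return segment_trials(counts, session, ann, MOTIF_LABELS, 0.015), session, ann


@pytest.fixture
def rng():
    return np.random.default_rng(0)
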