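import numpy as np
import pytest

from coatkit import SimulationConfig, TransitionRule, generate_tracks


@pytest.fixture(scope="session")
def rule():
    return TransitionRule()


@pytest.fixture(scope="session")
def noiseless_tracks():
    """Small noise-free track set under the AP2-plateau growth scenario."""
    cfg = SimulationConfig(n_tracks=10, noise_sigma=0.0, seed=101)
    return generate_tracks(cfg)


@pytest.fixture(scope="session")
def noisy_tracks():
    """Track set at the default 5% additive noise."""
    cfg = SimulationConfig(n_tracks=50, noise_sigma=0.05, seed=102)
    return generate_tracks(cfg)


@pytest.fixture(scope="session")
def two_phase_tracks_noiseless():
    cfg = SimulationConfig(n_tracks=10, model="two_phase", noise_sigma=0.0, seed=103)
    return generate_tracks(cfg)


def make_track(times, ap2, clc=None, track_id="t0", **kw):
    from coatkit import IntensityTrack

    return IntensityTrack(
        track_id=track_id,
        times=np.asarray(times, float),
        ap2=np.asarray(ap2, float),
        clc=None if clc is None else np.asarray(clc, float),
        **kw,
    )
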