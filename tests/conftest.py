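import numpy as np
import pytest

import locomode as lm


@pytest.fixture(scope="session")
def small_sim():
    """A short, well-separated simulated session with its ground truth."""
    cfg = lm.SimConfig(seed=101, n_rounds=2)
    session, truth = lm.generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    _, session, _ = small_sim
    return lm.analyze_session(session, session_id="small")


@pytest.fixture(scope="session")
def small_bank(small_analysis):
    return lm.train_bank(small_analysis.windows)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_915)


def make_session(
    n_channels=3, n_samples=400, fs=2000.0, seed=0, markers=(), with_grf=True
):
    """A minimal hand-built session for I/O and edge-case tests."""
    r = np.random.default_rng(seed)
    channels = [
        lm.ChannelSpec(f"emg_{i}", lm.Modality.EMG, units="mV")
        for i in range(n_channels - 1 if with_grf else n_channels)
    ]
    if with_grf:
        channels.append(lm.ChannelSpec("grf", lm.Modality.GRF, units="N"))
    signals = r.standard_normal((len(channels), n_samples))
    return lm.SessionRecording(
        fs_hz=fs,
        signals=signals,
        channels=channels,
        markers=list(markers),
        body_weight_n=700.0,
    )
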