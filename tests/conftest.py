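import numpy as np
import pytest

import erdbci as e

FS = 256


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine_segment(freq, amplitude, seconds=6.0, labels=("C3", "Cz", "C4"), fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return e.EEGSegment(np.tile(x[:, None], (1, len(labels))), fs, list(labels))


def make_trial_store(user, n_per_class, seed=0, labels=(e.NON_CONTROL, e.LEFT, e.RIGHT)):
    """Feed cue-structured trials from a simulated user into a TrialStore.

    Open-loop equivalent of the paradigm's collection phase: 2 s fixation,
    5 s task, processed through the standard feature pipeline.
    """
    pipe = e.FeaturePipeline()
    store = e.TrialStore(e.BandPowerConfig().feature_ids)
    i0, i1 = 3 * FS, 7 * FS
    order = [lbl for _ in range(n_per_class) for lbl in labels]
    for lbl in order:
        scheduled = np.array(
            [e.NON_CONTROL] * (2 * FS) + [lbl] * (5 * FS) + [e.NON_CONTROL] * (2 * FS),
            dtype=object,
        )
        seg = user.generate(scheduled)
        bip, feats = pipe.process(seg)
        track = feats.values[i0:i1]
        store.add(
            e.Trial(
                label=lbl,
                feature_track=track,
                feature_means=track.mean(axis=0),
                eeg=e.EEGSegment(bip.data[: 7 * FS], FS, list(bip.channel_labels)),
            )
        )
    return store


@pytest.fixture(scope="session")
def strong_session():
    """One full co-adaptive closed-loop session of a strong-ERD user."""
    user = e.SimUser(e.preset("strong"), seed=1)
    result = e.run_coadaptive_session(user, seed=1)
    return user, result


@pytest.fixture(scope="session")
def strong_model(strong_session):
    _, result = strong_session
    assert result.model is not None
    return result.model
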