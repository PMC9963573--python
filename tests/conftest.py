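import numpy as np
import pytest

import eegverify as ev

FS = 500.0


def make_recording(data: np.ndarray, fs: float = FS, subject: str = "subA",
                   session: int = 1, role: str = "genuine") -> ev.Recording:
    """Wrap a (19, n) array as a Recording."""
    return ev.Recording(subject_id=subject, session_index=session,
                        data=data, fs=fs, role=role)


def sine_recording(freq_hz: float, amp: float = 1.0, duration_s: float = 60.0,
                   fs: float = FS) -> ev.Recording:
    t = np.arange(int(duration_s * fs)) / fs
    wave = amp * np.sin(2 * np.pi * freq_hz * t)
    return make_recording(np.tile(wave, (19, 1)), fs=fs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 genuine subjects x 3 sessions + 1 impostor, in memory."""
    cfg = ev.CohortConfig(n_genuine=3, n_sessions=3, n_impostors=1,
                          master_seed=42)
    return ev.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_store(tiny_cohort):
    return ev.assemble_features(tiny_cohort, scale="dB")


@pytest.fixture(scope="session")
def fake_manifest():
    """Paper-shaped manifest (29 x 20 + 23) without any signal synthesis."""
    entries = []
    for i in range(29):
        for sess in range(1, 21):
            entries.append({"subject_id": f"sub{i + 1:02d}",
                            "session_index": sess, "role": "genuine",
                            "seed": 0, "path": None})
    for j in range(23):
        entries.append({"subject_id": f"imp{j + 1:02d}", "session_index": 1,
                        "role": "impostor", "seed": 0, "path": None})
    return entries


@pytest.fixture(scope="session")
def fake_store():
    """Random-feature store over the paper-shaped manifest (no training use).

    4 segments per session keep it light; values are positive so both
    scales are valid.
    """
    rng = np.random.default_rng(0)
    feats = []
    for i in range(29):
        for sess in range(1, 21):
            for seg in range(1, 5):
                feats.append(ev.SegmentFeatures(
                    subject_id=f"sub{i + 1:02d}", session_index=sess,
                    segment_index=seg,
                    values=rng.uniform(0.5, 2.0, 855), scale="raw"))
    return ev.FeatureStore.from_features(feats)
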