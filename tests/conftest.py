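import numpy as np
import pytest

import sozpu


@pytest.fixture(scope="session")
def bench():
    """Shared synthetic benchmark: one generator-default recording, extracted once.

    8 channels (4 SOZ / 4 non-SOZ) x 30 minutes at 512 Hz -> 720 labeled
    20-s segments with 48 entropy features each, plus the 8x6 entropy-matrix
    images for the convolutional path.
    """
    cfg = sozpu.SynthConfig(n_soz=4, n_nonsoz=4, duration_s=1800.0, seed=7)
    rec, log = sozpu.generate_recording(cfg)
    segments = sozpu.segment_recording(rec)
    ext = sozpu.EntropyFeatureExtractor().fit(segments)
    X = ext.transform(segments)
    y = np.array([s.label for s in segments], dtype=object)
    n_bands = len(ext.bands_)
    mats = X.reshape(len(X), len(sozpu.ENTROPY_NAMES), n_bands)
    lo = mats.min(axis=(1, 2), keepdims=True)
    hi = mats.max(axis=(1, 2), keepdims=True)
    images = (mats - lo) / np.where(hi - lo > 0, hi - lo, 1.0)
    return {
        "cfg": cfg,
        "recording": rec,
        "event_log": log,
        "segments": segments,
        "X": X,
        "y": y,
        "images": images,
        "names": ext.feature_names_,
        "extractor": ext,
    }


@pytest.fixture()
def gaussian_blobs():
    """Well-separated 2-D Gaussian classes for fast classifier checks."""

    def make(n_per_class=200, sep=4.0, seed=0, labels=("NONSOZ", "SOZ")):
        rng = np.random.default_rng(seed)
        Xn = rng.normal(loc=(-sep / 2, 0), scale=1.0, size=(n_per_class, 2))
        Xp = rng.normal(loc=(+sep / 2, 0), scale=1.0, size=(n_per_class, 2))
        X = np.vstack([Xn, Xp])
        y = np.array([labels[0]] * n_per_class + [labels[1]] * n_per_class, dtype=object)
        return X, y

    return make
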