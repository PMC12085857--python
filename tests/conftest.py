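import numpy as np
import pytest

from ecgmi.records import MIParams, SynthConfig
from ecgmi.synth import generate_record


@pytest.fixture
def clean_record():
    """10 s, 60 bpm, 1000 Hz, jitter-free single lead."""
    return generate_record(SynthConfig(duration_s=10, heart_rate_bpm=60, fs=1000, seed=0))


@pytest.fixture
def clean_mi_record():
    return generate_record(SynthConfig(duration_s=10, heart_rate_bpm=60, fs=1000,
                                       mi=True, mi_params=MIParams(), seed=0))


@pytest.fixture
def two_lead_record():
    return generate_record(SynthConfig(duration_s=10, heart_rate_bpm=70, fs=500,
                                       n_leads=2, seed=3))


def make_separable_features(n=300, d_total=4, seed=0, shuffle_labels=False):
    """Linearly separable 2-class features: 2 informative dims with class
    centres (+2, -2) vs (-2, +2) and within-class noise 0.3 (>13 sigma
    separation), plus nuisance standard-normal dims."""
    rng = np.random.default_rng(seed)
    y = np.array(["MI"] * (n // 2) + ["HC"] * (n - n // 2))
    X = rng.standard_normal((n, d_total))
    X[:, :2] *= 0.3
    X[: n // 2, 0] += 2.0
    X[: n // 2, 1] -= 2.0
    X[n // 2 :, 0] -= 2.0
    X[n // 2 :, 1] += 2.0
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    if shuffle_labels:
        rng.shuffle(y)
    return X, y
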