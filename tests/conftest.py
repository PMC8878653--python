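import numpy as np
import pytest

import myograsp as mg


@pytest.fixture(scope="session")
def subject_features():
    """A balanced 128-window two-class feature set from one synthetic subject."""
    rec = mg.make_subject_dataset(mg.SynthParams(seed=101), n_reps=10, hold_s=5.0)
    cond = mg.condition_signal(rec)
    fs = mg.extract_features(mg.segment(cond), sampling_rate=cond.sampling_rate)
    two = fs.restrict_classes([mg.GestureLabel.GRASP, mg.GestureLabel.OPEN])
    return mg.subsample_per_class(two, 64, seed=101)


@pytest.fixture(scope="session")
def trained_model(subject_features):
    train, _ = mg.split_dataset(subject_features, mg.SplitSpec(seed=101))
    return mg.fit_lda(train)


@pytest.fixture(scope="session")
def reference_finger():
    return mg.make_reference_geometry()


def gaussian_problem(rng, d=None, n=None, sep=2.0):
    """Random two-class Gaussian feature set for classifier tests."""
    d = d or int(rng.integers(2, 6))
    n = n or int(rng.integers(10, 101))
    mu = rng.normal(0, 1, d)
    offset = rng.normal(0, 1, d)
    offset *= sep / np.linalg.norm(offset)
    X = np.vstack([rng.normal(mu, 1.0, (n, d)),
                   rng.normal(mu + offset, 1.0, (n, d))])
    labels = np.array(["a"] * n + ["b"] * n, dtype=object)
    return mg.LabeledFeatureSet(X, labels, [f"f{i}" for i in range(d)])
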