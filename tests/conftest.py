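import numpy as np
import pytest

from cogdraw import ConvAttClassifier, simulate_cohort
from cogdraw.synthetic import TASKS


def stack_images(subjects):
    """(n, 3 tasks, 3 ch, S, S) ink-positive array from synthetic subjects."""
    return np.stack([
        np.stack([np.repeat((1.0 - s.images[t].astype(np.float32) / 255.0)[None],
                            3, axis=0) for t in TASKS])
        for s in subjects])


@pytest.fixture(scope="session")
def small_cohort():
    subs = simulate_cohort(60, "uniform", rng_seed=42, canvas_size=64,
                           noise_sd=1.0)
    X = stack_images(subs)
    y = np.array([s.moca_like_score for s in subs])
    return subs, X, y


@pytest.fixture(scope="session")
def trained_toy(small_cohort):
    """A briefly trained multi-input Conv-Att model for structural tests."""
    _, X, y = small_cohort
    est = ConvAttClassifier.toy(epochs=4, random_state=0)
    est.fit(X, y)
    return est


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    from cogdraw import generate_cohort
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(12, "uniform", out_dir=out, rng_seed=3, canvas_size=64,
                    noise_sd=1.0)
    return out
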