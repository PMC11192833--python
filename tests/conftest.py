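import numpy as np
import pytest

from orthomem.inference import FitConfig
from orthomem.synthetic_data import StudyDesign, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_word_pairs():
    """Random letter-string pairs (lengths 1-8) for property checks."""
    gen = np.random.default_rng(7)
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    pairs = []
    for _ in range(150):
        w1 = "".join(gen.choice(letters, size=gen.integers(1, 9)))
        w2 = "".join(gen.choice(letters, size=gen.integers(1, 9)))
        pairs.append((w1, w2))
    return pairs


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by analysis/io tests."""
    design = StudyDesign(n_participants=2, n_test_trials=120, pool_size=400)
    trials, truth = simulate_study(design, FitConfig(), seed=5)
    return trials, truth
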