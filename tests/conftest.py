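import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nasga.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient synthetic cohort shared across cohort-level tests."""
    config = SynthConfig(n_patients=200, seed=7)
    tables, demographics, truth = generate_cohort(config)
    return config, tables, demographics, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_toy_episodes(
    n: int, seed: int, n_features: int = 8, hours: int = 5, offset: float = 1.5
):
    """Linearly separable episode batches: positives carry a mean offset."""
    gen = np.random.default_rng(seed)
    y = gen.integers(0, 2, size=n)
    x = gen.normal(0.0, 1.0, size=(n, hours, n_features))
    x[y == 1] += offset / np.sqrt(n_features)
    return x, y
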