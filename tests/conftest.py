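import numpy as np
import pytest

from ecgquant import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A small but two-sided cohort: 8 subjects per group, 80 beats each."""
    healthy = sim.healthy_default(n_subjects=8, beats_per_subject=80)
    disease = sim.disease_default(n_subjects=8, beats_per_subject=80)
    return sim.simulate_beat_table(healthy, disease, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def default_shape():
    return sim.BeatShape()
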