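import numpy as np
import pytest

from chefind.enrichment import estimate_dispersion, test_fraction_enrichment
from chefind.simulate import (
    SimulationConfig,
    simulate_class_counts,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: 300 expressed transcripts + 700 noise,
    four 1-Mb chromosomes, tracks, peaks and motifs."""
    return simulate_dataset(SimulationConfig(seed=1), with_tracks=True)


@pytest.fixture(scope="session")
def class_sim():
    """Planted enrichment simulation: 200 cheRNA / 200 sneRNA at |log2FC|=2,
    600 null; NB dispersion 0.1; 5+5 replicates; seed 1."""
    counts, truth = simulate_class_counts(seed=1)
    return counts, truth


@pytest.fixture(scope="session")
def class_sim_calls(class_sim):
    counts, truth = class_sim
    disp = estimate_dispersion(counts)
    calls = test_fraction_enrichment(counts, disp)
    return calls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
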