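import numpy as np
import pytest

from apskew.synthetic import SyntheticSpec, plant_peaks, simulate_tracks, truth_catalog
from apskew.tracks_io import CoverageTrack, GenomeTable


@pytest.fixture
def small_genome():
    return GenomeTable((("chr1", 1000), ("chr2", 500)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_track(genome, rng, density=0.3, scale=10.0, label="rand"):
    data = {}
    for name, length in genome.entries:
        arr = rng.random(length) * scale
        arr[rng.random(length) > density] = 0.0
        data[name] = arr
    return CoverageTrack(genome, data, label=label)


@pytest.fixture(scope="session")
def sim_world():
    """One moderately sized simulated world shared across tests."""
    spec = SyntheticSpec(n_peaks=120, seed=42)
    truth = plant_peaks(spec)
    ant, post, whole = simulate_tracks(truth, spec)
    return spec, truth, ant, post, whole, truth_catalog(truth)
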