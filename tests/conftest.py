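import numpy as np
import pytest

from difscan.config import PipelineConfig
from difscan.iterated_pipeline import run_phylum
from difscan.seed_fuzzy import SeedDif
from difscan.synthetic_data import CladeSpec, evolve_clade


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genome(rng, length=5000, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def default_study():
    """The standard synthetic study: 30 genomes in 6 genera."""
    spec = CladeSpec()
    chroms, truth = evolve_clade(spec)
    return spec, chroms, truth


@pytest.fixture(scope="session")
def default_study_result(default_study):
    """Full pipeline run on the standard study (shared across tests)."""
    spec, chroms, truth = default_study
    seed = SeedDif(organism=chroms[0].organism, sequence=spec.root_dif)
    result = run_phylum(chroms, seed, chroms[0].organism, PipelineConfig())
    return spec, chroms, truth, result
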