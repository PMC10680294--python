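import numpy as np
import pandas as pd
import pytest

from cellcis.simulate import SimulationConfig, simulate_genotypes
from cellcis.types import GenotypeMatrix


@pytest.fixture
def config():
    return SimulationConfig(n_samples=20, seed=7)


@pytest.fixture
def genotypes(config):
    return simulate_genotypes(config, n_variants=60, spacing_bp=1000)


@pytest.fixture
def tiny_genotypes():
    """Hand-built 6-sample x 3-variant matrix with one missing call."""
    samples = [f"S{i}" for i in range(6)]
    ids = ["v1", "v2", "v3"]
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": [101, 201, 301], "ref": "A", "alt": "G"},
        index=pd.Index(ids, name="variant"),
    )
    dosages = pd.DataFrame(
        [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 1], [1, 0, 0], [np.nan, 1, 2]],
        index=samples, columns=ids, dtype=float,
    )
    return GenotypeMatrix(variants, dosages)
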