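import numpy as np
import pandas as pd
import pytest

from radintro.genotypes import GenotypeMatrix


def make_matrix(genotypes, species, zone=None, population=None,
                scaffold=None, position=None, ref=None, alt=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "species": species,
        "population": population or ["pop"] * n,
        "zone": zone or ["allopatric"] * n,
    })
    return GenotypeMatrix(
        genotypes=g,
        scaffold=np.asarray(scaffold if scaffold is not None
                            else ["sc1"] * m),
        position=np.asarray(position if position is not None
                            else np.arange(1, m + 1)),
        ref=np.asarray(ref if ref is not None else ["A"] * m),
        alt=np.asarray(alt if alt is not None else ["T"] * m),
        samples=samples)


@pytest.fixture(scope="session")
def tiny_fixture_paths(tmp_path_factory):
    from radintro.pipeline import make_fixture
    out = tmp_path_factory.mktemp("tiny_fixture")
    return make_fixture("tiny", seed=7, outdir=out)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """Noise-free study-scale dataset with planted hybrids, paralogs and an
    introgressed two-scaffold block (shared across tests for speed)."""
    from radintro.pipeline import fixture_spec
    from radintro.sim.genotypes import simulate_genotype_dataset

    spec = fixture_spec("paper_scale")
    spec.missing_rate = 0.0
    spec.artefact_het_prob = 1.0
    matrix, truth = simulate_genotype_dataset(spec, seed=20454)
    return matrix, truth
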