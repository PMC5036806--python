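import numpy as np
import pytest

from episcan import simdata


@pytest.fixture(scope="session")
def sparse_map():
    """10 markers on 2 linkage groups, 20 cM spacing (weak linkage)."""
    return simdata.default_map(n_markers=10, n_groups=2, length_cm=160.0)


@pytest.fixture(scope="session")
def pop147(sparse_map):
    """147 fully homozygous RILs on the sparse map."""
    return simdata.simulate_ril_genotypes(sparse_map, 147, seed=11)


def make_pheno(env_id, values):
    return simdata.PhenotypeSet(env_id, dict(values))


@pytest.fixture()
def noise_pheno(pop147):
    rng = np.random.default_rng(42)
    return simdata.PhenotypeSet(
        "NOISE", dict(zip(pop147.line_ids, rng.normal(20.0, 0.5, pop147.n_lines)))
    )
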