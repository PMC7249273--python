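import numpy as np
import pytest

from skimprobe import SimConfig, make_gene_space, run_all


@pytest.fixture(scope="session")
def gene_space():
    """Default-condition synthetic gene space (seed 1, 30 loci)."""
    return make_gene_space(SimConfig(seed=1, n_loci=30))


@pytest.fixture(scope="session")
def pipeline_result(gene_space):
    """Full pipeline run over the session gene space, evaluation included."""
    return run_all(gene_space)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
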