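import numpy as np
import pytest

from wgtkit.core_io import GeneModel, Genome
from wgtkit.pipeline import run_on_simulation
from wgtkit.simulate import SimConfig, simulate


def make_genome(name, layout, gene_len=1000, gap=1000):
    """Build a genome from {chrom: n_genes} or {chrom: [gene ids]}.

    Genes are laid out uniformly: start = i*(gene_len+gap), so rank == index.
    """
    genes = []
    for chrom, spec in layout.items():
        ids = [f"{chrom}_g{i}" for i in range(spec)] if isinstance(spec, int) else spec
        for i, gid in enumerate(ids):
            s = i * (gene_len + gap)
            genes.append(GeneModel(gid, chrom, s, s + gene_len, "+"))
    return Genome(name, genes)


@pytest.fixture(scope="session")
def default_sim():
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_sim):
    return run_on_simulation(default_sim)


@pytest.fixture(scope="session")
def quiet_sim():
    """Rearrangement-free triplication: every stage should recover exactly."""
    return simulate(SimConfig(seed=13, n_rearrangements=0))


@pytest.fixture(scope="session")
def quiet_run(quiet_sim):
    return run_on_simulation(quiet_sim)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
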