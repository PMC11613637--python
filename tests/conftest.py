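import random

import pytest

from panfam import SimulationConfig, family_queries, simulate_pangenome

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def study_sim():
    """Study-mirroring synthetic pan-genome (5 cultivars, 8 core + 5
    dispensable + 2 unique groups), shared across tests."""
    cfg = SimulationConfig(seed=11)
    genomes, truth = simulate_pangenome(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """The same pan-genome written to disk as a FASTA/GFF3/TSV bundle."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=11)
    genomes, truth = simulate_pangenome(cfg, outdir)
    from panfam.genome_model import write_fasta

    write_fasta(family_queries(cfg), outdir / "queries.faa")
    return cfg, genomes, truth, outdir


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(n))
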