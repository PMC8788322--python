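import pytest

from magscreen import simulate
from magscreen.genome_io import GeneAnnotation, GenomeSequence


@pytest.fixture
def toy_genome():
    # one 60 nt scaffold with a single gene at 11..40
    seq = "ACGTACGGTTCAGATTACCGGATCGGCATCAAGTTCCGGATTAGCCGATTAGGCATCAGA"
    return [GenomeSequence("s1", seq)]


@pytest.fixture
def toy_genes():
    return [GeneAnnotation("geneA", "s1", 11, 40, "+", product="toy")]


@pytest.fixture(scope="session")
def default_screen():
    """Seeded default-scale simulation shared across tests: 200 genes,
    10% essential, ~34 central strains/gene, 3 replicates, no planted
    effects (null screen)."""
    cfg = simulate.SimConfig(seed=11)
    genome, genes, truth = simulate.simulate_genome(cfg)
    pool = simulate.simulate_pool(genome, genes, truth, cfg)
    matrix, sheet, latents = simulate.simulate_selection(pool, truth, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "pool": pool,
        "matrix": matrix,
        "sheet": sheet,
        "latents": latents,
    }


@pytest.fixture(scope="session")
def effect_screen():
    """Simulation with planted retention effects spanning log2(p_g/p_wt)
    in [-2, +0.5] around a wild-type retention of 0.7, plus the defect
    gene 0.45-vs-0.9 checked separately at default p_wt."""
    import numpy as np

    p_wt = 0.7
    ratios = np.linspace(-2.0, 0.5, 24)
    effects = {i: float(p_wt * 2.0**r) for i, r in enumerate(ratios)}
    cfg = simulate.SimConfig(seed=23, p_wt=p_wt, retention_effects=effects)
    genome, genes, truth = simulate.simulate_genome(cfg)
    pool = simulate.simulate_pool(genome, genes, truth, cfg)
    matrix, sheet, _ = simulate.simulate_selection(pool, truth, cfg)
    return {
        "config": cfg,
        "genes": genes,
        "truth": truth,
        "pool": pool,
        "matrix": matrix,
        "sheet": sheet,
    }
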