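import numpy as np
import pytest

import gsel


@pytest.fixture(scope="session")
def ld_panel():
    """Mid-size simulated panel with appreciable LD, shared across tests."""
    cfg = gsel.SimConfig(
        n_samples=300,
        n_markers=600,
        n_chromosomes=6,
        chromosome_length_bp=1_000_000,
        ld_decay_bp=50_000,
        n_qtl=10,
        target_h2=0.5,
        seed=11,
    )
    return cfg, gsel.sim_genotypes(cfg)


@pytest.fixture(scope="session")
def oligo_trait(ld_panel):
    """A 10-QTL h2=0.5 trait on the shared panel, standardized."""
    cfg, g = ld_panel
    y, truth = gsel.sim_phenotype(g, cfg)
    return gsel.standardize(y), truth


def toy_matrix(dosages, chrom="1", start=100, spacing=100, samples=None):
    """Small GenotypeMatrix from a literal dosage array (one chromosome)."""
    d = np.asarray(dosages)
    n, m = d.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    markers = [
        gsel.MarkerRecord(f"mk{j}", chrom, start + j * spacing) for j in range(m)
    ]
    return gsel.GenotypeMatrix(samples, markers, d)


@pytest.fixture
def toy():
    return toy_matrix
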