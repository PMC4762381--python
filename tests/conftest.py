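import numpy as np
import pandas as pd
import pytest

import nonzein as nz


@pytest.fixture(scope="session")
def small_experiment():
    """A small synthetic experiment with planted rebalancing in o2/fl2."""
    cfg = nz.SimulationConfig(n_proteins=300, seed=7)
    counts, catalog, truth = nz.simulate_experiment(cfg)
    return cfg, counts, catalog, truth


@pytest.fixture(scope="session")
def small_nsaf(small_experiment):
    _, counts, catalog, _ = small_experiment
    corrected = nz.add_spectral_fraction(counts, 0.05)
    return nz.nsaf(corrected, catalog, scale=1e6)


def make_counts(values, genotypes, replicates=None, protein_ids=None, zero_corrected=False):
    """Build a SpectralCountMatrix from a 2-D array and per-sample genotypes."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(n_prot)]
    sample_ids = [f"s{i}" for i in range(n_samp)]
    if replicates is None:
        seen = {}
        replicates = []
        for g in genotypes:
            seen[g] = seen.get(g, 0) + 1
            replicates.append(seen[g])
    meta = pd.DataFrame(
        {"genotype": genotypes, "replicate": replicates}, index=sample_ids
    )
    df = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    return nz.SpectralCountMatrix(df, meta, zero_corrected=zero_corrected)


@pytest.fixture
def uniform_catalog():
    """Ten proteins of identical composition (all 20 residues, length 200)."""
    seq = "ACDEFGHIKLMNPQRSTVWY" * 10
    return nz.ProteinCatalog({f"P{i}": seq for i in range(10)})
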