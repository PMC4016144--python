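import numpy as np
import pandas as pd
import pytest

from triomix.simulate import SimConfig, simulate_ground_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Toy study: 300 genes, sparse but quick."""
    return SimConfig(
        n_genes=300,
        n_spectra_total=3000,
        n_reads_total=30000,
        probes_per_gene_range=(2, 3),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_ground_truth(small_config)


def random_psm_table(rng, n, decoy_frac=0.2, n_proteins=30, shared_frac=0.1):
    """Unstructured random PSM table for oracle-equivalence tests."""
    prot = [f"P{i}" for i in range(n_proteins)]
    groups = []
    for _ in range(n):
        if rng.random() < shared_frac:
            a, b = rng.choice(n_proteins, size=2, replace=False)
            groups.append(f"{prot[a]};{prot[b]}")
        else:
            groups.append(prot[rng.integers(n_proteins)])
    return pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "peptide": [f"pep{rng.integers(200)}" for _ in range(n)],
            "proteins": groups,
            "probability": np.round(rng.random(n), 3),
            "is_decoy": (rng.random(n) < decoy_frac).astype(int),
        }
    )
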