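import numpy as np
import pandas as pd
import pytest

from germdecon.genotypes import MISSING, GenotypeMatrix, _default_meta, _default_snps
from germdecon.synthetic_data import SimulationConfig, simulate_collection


def make_gm(dosage, ploidy=2, ref=None, alt=None, ids=None, snp_ids=None,
            meta_overrides=None):
    """Hand-build a small GenotypeMatrix (depths default to 20x per allele)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    ids = ids or [f"A{i+1}" for i in range(n)]
    pl = np.full(n, ploidy) if np.isscalar(ploidy) else np.asarray(ploidy)
    if ref is None:
        f = np.where(dosage == MISSING, 0, dosage) / pl[:, None]
        alt = np.rint(40 * f).astype(np.int32)
        ref = np.where(dosage == MISSING, 0, 40 - alt).astype(np.int32)
        alt = np.where(dosage == MISSING, 0, alt)
    meta = _default_meta(ids, pl)
    if meta_overrides:
        for col, values in meta_overrides.items():
            meta[col] = values
    snps = _default_snps(snp_ids or [f"snp{j+1}" for j in range(m)])
    return GenotypeMatrix(dosage, np.asarray(ref), np.asarray(alt), meta, snps)


@pytest.fixture(scope="session")
def clone_collection():
    """Collection with biological and technical clone sets at replicate-
    calibrated error rates (shared across tests; treat as read-only)."""
    cfg = SimulationConfig(
        seed=421, n_snps=3000, n_subpops=3, n_genotypes_per_subpop=10,
        fst=0.2, default_ploidy=4,
        clone_copies={f"G{k:03d}": 3 for k in range(1, 13)},
    )
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def structured_diploid():
    """Three diploid sub-populations at fst 0.3, no clones."""
    cfg = SimulationConfig(seed=7, n_snps=1000, n_subpops=3,
                           n_genotypes_per_subpop=8, fst=0.3, default_ploidy=2)
    return simulate_collection(cfg)
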