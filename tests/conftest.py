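import numpy as np
import pytest

from paima import cohort as ch
from paima import fixtures as fx


@pytest.fixture(scope="session")
def panel():
    return fx.load_panel_fixture()

@pytest.fixture(scope="session")
def table2():
    return fx.variant_table()

@pytest.fixture(scope="session")
def variant_records():
    return fx.load_variants()


def make_dataset(genotypes, phenotype, provenance="observed"):
    """CohortDataset from raw arrays with placeholder variant metadata."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    recs = ch.synthetic_records(genotypes.shape[1])
    return ch.CohortDataset(genotypes, np.asarray(phenotype, dtype=np.int8), recs, provenance)


def xor_dataset(n_cases=400, n_controls=400, p=10, seed=0, high=0.9, low=0.1):
    """Balanced cohort with an XOR pair planted at columns (0, 1).

    The planted loci have allele frequency 0.5 (no marginal effect);
    background loci draw frequencies from U(0.1, 0.5).
    """
    rng = np.random.default_rng(seed)
    mafs = np.concatenate([[0.5, 0.5], rng.uniform(0.1, 0.5, p - 2)])
    pool = ch.sample_cases(mafs, max(4000, 5 * (n_cases + n_controls)), seed=seed + 1)
    model = ch.PenetranceModel.parity((0, 1), high=high, low=low)
    return ch.plant_epistasis(pool, model, n_cases, n_controls, seed=seed + 2)


def parity3_dataset(n_cases=400, n_controls=400, p=8, seed=0, high=0.9, low=0.1):
    """Balanced cohort with a 3-way parity triple planted at columns (0, 1, 2)."""
    rng = np.random.default_rng(seed)
    mafs = np.concatenate([[0.5, 0.5, 0.5], rng.uniform(0.1, 0.5, p - 3)])
    pool = ch.sample_cases(mafs, max(4000, 5 * (n_cases + n_controls)), seed=seed + 1)
    model = ch.PenetranceModel.parity((0, 1, 2), high=high, low=low)
    return ch.plant_epistasis(pool, model, n_cases, n_controls, seed=seed + 2)
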