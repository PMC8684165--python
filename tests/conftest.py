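import numpy as np
import pandas as pd
import pytest

import coexsig as cx


@pytest.fixture(scope="session")
def small_cohort():
    """300 genes, two 50-gene modules, one carrying a disease effect."""
    cfg = cx.SyntheticConfig(
        n_genes=300, module_sizes=(50, 50), disease_modules=(0,),
        disease_effect=1.5, n_cases=15, n_samples=30, seed=42,
    )
    return cx.generate_dataset(cfg)


@pytest.fixture(scope="session")
def family_cohort():
    """Four families of two samples with planted family offsets."""
    cfg = cx.SyntheticConfig(
        n_genes=200, module_sizes=(40,), n_samples=8, n_families=4,
        n_cases=1, family_offsets_sd=1.0, noise_sd=0.5, seed=7,
    )
    return cx.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_expr(rng):
    x = rng.standard_normal((20, 10))
    return pd.DataFrame(
        x, index=[f"g{i}" for i in range(20)], columns=[f"s{j}" for j in range(10)]
    )
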