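import numpy as np
import pandas as pd
import pytest

from funrarity import (AssemblageMatrix, GridSpec, SimConfig, TraitTable,
                       simulate_world)


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared across tests (seed 11)."""
    return simulate_world(SimConfig(seed=11))


@pytest.fixture(scope="session")
def structureless_world():
    """World with no planted structure and no richness gradient (seed 5)."""
    cfg = SimConfig(n_species=300, n_planted_rare=0,
                    richness_gradient_strength=0.0, missingness_fraction=0.0,
                    seed=5)
    return simulate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_assemblage(rng, n_species, n_cells, density=0.3):
    """Random binary assemblage with no empty rows/columns."""
    while True:
        m = (rng.random((n_species, n_cells)) < density).astype(np.int8)
        if m.sum(axis=1).all() and m.sum(axis=0).all():
            break
    df = pd.DataFrame(
        m,
        index=[f"sp{i:03d}" for i in range(n_species)],
        columns=[f"r0c{j}" for j in range(n_cells)],
    )
    df.index.name = "species"
    df.columns.name = "cell_id"
    return AssemblageMatrix(df, GridSpec(), "test")


def random_trait_table(rng, n_species, n_cont, n_cat, n_levels=3):
    """Random mixed-type trait table with no missing values."""
    data = {}
    kinds = {}
    for i in range(n_cont):
        data[f"c{i}"] = rng.normal(size=n_species)
        kinds[f"c{i}"] = "continuous"
    for i in range(n_cat):
        data[f"k{i}"] = rng.choice([f"L{j}" for j in range(n_levels)], n_species)
        kinds[f"k{i}"] = "categorical"
    df = pd.DataFrame(data, index=[f"sp{i:03d}" for i in range(n_species)])
    df.index.name = "species"
    return TraitTable(df, kinds)
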