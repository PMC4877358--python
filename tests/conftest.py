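import warnings

import numpy as np
import pandas as pd
import pytest

import darkdiv as dd

warnings.filterwarnings("ignore", message=".*species never recorded.*")


@pytest.fixture
def toy_occurrence():
    """Three plots, three species: P1={A,B}, P2={A,C}, P3={B,C}."""
    df = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1], [0, 1, 1]],
        index=["P1", "P2", "P3"],
        columns=["A", "B", "C"],
        dtype=float,
    )
    return dd.OccurrenceMatrix(df)


def random_occurrence(rng, n_plots=20, n_species=15, p=0.3):
    """Random binary matrix with every plot and species non-empty w.h.p."""
    X = (rng.random((n_plots, n_species)) < p).astype(float)
    plots = [f"P{i:02d}" for i in range(n_plots)]
    species = [f"S{j:02d}" for j in range(n_species)]
    return dd.OccurrenceMatrix(pd.DataFrame(X, index=plots, columns=species))


@pytest.fixture(scope="session")
def benchmark():
    """Shared benchmark run: synthetic truth, train/test split, the three
    estimators and their dark diversities."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = dd.simulate_metacommunity(dd.SimConfig(seed=7))
        train, test = dd.split_train_test(truth, test_plots_per_habitat=10, seed=1)
        models = dd.fit_sdm(
            train["occurrence"], train["env"], min_occ=10, criterion="tss", seed=3
        )
        pools = {
            "beals": dd.beals_estimate(train["occurrence"], test["occurrence"]),
            "ellenberg": dd.ellenberg_estimate(
                test["occurrence"], truth.indicators, k=2.0
            ),
            "sdm": dd.sdm_pool(
                models, test["env"], species_universe=list(train["occurrence"].species_ids)
            ),
        }
        darks = {
            name: dd.dark_from_pool(pool, test["occurrence"])
            for name, pool in pools.items()
        }
    return {
        "truth": truth,
        "train": train,
        "test": test,
        "models": models,
        "pools": pools,
        "darks": darks,
    }
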