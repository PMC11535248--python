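import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # expose tests/oracles.py

from tracevar import (
    FeatureMeta,
    FeatureTable,
    SimConfig,
    VariantKey,
    generate_dataset,
    impute_missing,
)

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

SMALL_TISSUES = ("heart", "liver", "skeletal_muscle", "skin", "whole_blood", "lung")


@pytest.fixture(scope="session")
def data_dir() -> str:
    return DATA_DIR


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated study shared across read-only tests."""
    cfg = SimConfig(n_genes=150, n_variants=1500, tissues=SMALL_TISSUES, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_sim):
    return impute_missing(small_sim.features)


def make_toy_table(X: np.ndarray, gene_cycle: int = 7, origin: str = "variant") -> FeatureTable:
    """Wrap a numeric matrix in a FeatureTable with synthetic keys."""
    n, f = X.shape
    keys = [VariantKey("1", i + 1, "A", "C", f"G{i % gene_cycle}") for i in range(n)]
    meta = [
        FeatureMeta(f"x{j}", origin, "toy", "toy", "heart" if origin == "tissue" else None)
        for j in range(f)
    ]
    values = pd.DataFrame(X, index=[k.id for k in keys], columns=[m.name for m in meta])
    return FeatureTable(keys, meta, values)
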