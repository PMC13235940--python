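"""Shared fixtures: toy graphs, a small simulated dataset, trained models.

Model fits are expensive relative to everything else, so the recovery-fixture
models (three seeds × three graph-loss weights) are trained once per session
and shared by the tests that inspect them.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from geneprog import (
    GeneGraph,
    SimConfig,
    TrainConfig,
    generate,
    normalize_log,
)
from geneprog.training import fit as train_fit

# desk-scale training settings used throughout the suite; the reference
# defaults (lr 1e-4, 50k epochs) are far beyond interactive test budgets
DESK_LR = 1e-3
DESK_EPOCHS = dict(max_epochs=2000, min_epochs=500, patience_epochs=300)


def small_sim_config(**overrides) -> SimConfig:
    """A fast, strongly separable configuration for plumbing tests."""
    base = dict(
        n_genes=60,
        n_modules=2,
        module_size=10,
        n_donors_per_class=4,
        cells_per_donor=10,
        p_in=0.5,
        p_out=0.02,
        effect_size=2.0,
        informative_modules=(0,),
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    ds = generate(small_sim_config())
    return ds, normalize_log(ds.expression)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The parameter-recovery study conditions: 5 planted modules of 20
    genes in a 300-gene universe, 3 informative, strong donor effect."""
    ds = generate(SimConfig(seed=1))
    return ds, normalize_log(ds.expression)


@pytest.fixture(scope="session")
def recovery_models(recovery_dataset):
    """Models for w ∈ {0, 2, 5} × seeds {1, 2, 3} on the recovery fixture."""
    ds, norm = recovery_dataset
    models = {}
    for w in (0.0, 2.0, 5.0):
        for seed in (1, 2, 3):
            cfg = TrainConfig(w=w, d=10, learning_rate=DESK_LR, seed=seed, **DESK_EPOCHS)
            models[(w, seed)] = train_fit(norm, ds.graph, cfg)
    return models


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric_graph(rng: np.random.Generator, p: int, density: float = 0.4) -> GeneGraph:
    """Random weighted symmetric adjacency with unit self-loops."""
    A = rng.random((p, p)) * (rng.random((p, p)) < density)
    A = np.triu(A, k=1)
    A = A + A.T + np.eye(p)
    return GeneGraph([f"G{i}" for i in range(p)], sp.csr_matrix(A))


def random_row_stochastic(rng: np.random.Generator, p: int, d: int) -> np.ndarray:
    S = rng.random((p, d)) + 1e-3
    return S / S.sum(axis=1, keepdims=True)
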