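"""Shared fixtures: small tasks, random Hill systems, and one trained model.

Training is the expensive step, so the trained adaptation model is built once
per session and shared by the interrogation-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from netdistill.hill import HillParams, HillSynthesis, sample_hill_params
from netdistill.interrogation import Topology
from netdistill.nn_synthesis import build_synthesis
from netdistill.tasks import make_adaptation_task
from netdistill.training import TrainConfig, train


@pytest.fixture(scope="session")
def adaptation_task():
    return make_adaptation_task()

@pytest.fixture(scope="session")
def quick_train_config():
    """Shortened training schedule for tests that only need a decent fit."""
    return TrainConfig(max_iterations=1500, patience_evals=30, seed=11)


@pytest.fixture(scope="session")
def trained_adaptation(adaptation_task, quick_train_config):
    """One trained adaptation model, shared across tests."""
    synth = build_synthesis(2, 1, (16, 16), "per_gene", seed=5)
    return train(synth, adaptation_task, quick_train_config)


def random_hill_system(n_genes: int, seed: int,
                       p_link: float = 0.6) -> HillSynthesis:
    """A random monotone Hill-function ground truth over ``n_genes`` genes
    plus one input, with every gene guaranteed at least one activator."""
    rng = np.random.default_rng(seed)
    n_reg = n_genes + 1
    while True:
        sign = rng.choice([1, 0, -1], size=(n_reg, n_genes),
                          p=[p_link / 2, 1 - p_link, p_link / 2])
        if all((sign[:, j] == 1).any() for j in range(n_genes)):
            break
    topo = Topology(n_genes=n_genes, n_inputs=1, sign=sign)
    params = sample_hill_params(topo, seed=rng)
    return HillSynthesis(topo, params)
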