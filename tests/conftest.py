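"""Shared fixtures: one desk-scale synthetic cohort and one trained model,
built once per session and reused wherever training cost would otherwise
dominate the suite."""

from __future__ import annotations

import numpy as np
import pytest

from resistnet.cohort import CohortSpec, simulate_cohort
from resistnet.pipeline import DESK_RESVAE
from resistnet.preprocess import zscore_genes
from resistnet.resvae import ResVAEClassifier


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def zmatrix(cohort):
    return zscore_genes(cohort["expression"])


@pytest.fixture(scope="session")
def labels01(cohort):
    return (cohort["response"]["label"] == "resistant").astype(int).to_numpy()


@pytest.fixture(scope="session")
def desk_model(zmatrix, labels01):
    """Res-VAE trained on the full desk cohort (the attribution fixture)."""
    clf = ResVAEClassifier(**DESK_RESVAE, seed=1)
    clf.fit(zmatrix.values, labels01)
    return clf


@pytest.fixture(scope="session")
def small_model(zmatrix, labels01):
    """A cheap 20-epoch model for interface-level tests."""
    clf = ResVAEClassifier(
        hidden_dims=(16, 16), latent_dim=4, batch_size=64, learning_rate=1e-3,
        weight_decay=0.1, num_epochs=20, beta=1.0, seed=0,
    )
    clf.fit(zmatrix.X[:300], labels01[:300])
    return clf


@pytest.fixture
def rng():
    return np.random.default_rng(0)
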