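"""Shared fixtures: one default simulation and one trained classifier.

Training is expensive relative to everything else, so the planted-motif
classifier (and its label-permuted control) are session-scoped and shared
by the classifier, attribution and end-to-end tests.
"""

import numpy as np
import pytest

from drnaprom.classifier import PromoterTransformer
from drnaprom.sim import (
    SimulationConfig,
    simulate_coverage,
    simulate_genome,
    simulate_labelled_sequences,
)


@pytest.fixture(scope="session")
def default_simulation():
    """Default study conditions: 100 kb, 200 TSSs, step x10, leakage 0.1, seed 7."""
    cfg = SimulationConfig(seed=7)
    genome, truth = simulate_genome(cfg)
    tracks = simulate_coverage(genome, truth, cfg)
    return cfg, genome, truth, tracks


@pytest.fixture(scope="session")
def planted_sequences():
    """2000 planted-TATAAT labelled sequences (mutation 0.1, L=50, seed 13)."""
    cfg = SimulationConfig(seed=13, motif_mutation_rate=0.1)
    table = simulate_labelled_sequences(1000, 50, cfg)
    return cfg, table


@pytest.fixture(scope="session")
def trained_model(planted_sequences):
    """Tiny-preset classifier fit on 1600 sequences with 400 held out.

    Returns (estimator, X_test, y_test, sim_config).
    """
    cfg, table = planted_sequences
    X = table["sequence"].tolist()
    y = (table["label"] == "promoter").astype(int).to_numpy()
    rng = np.random.default_rng(13)
    idx = rng.permutation(len(X))
    test_idx, train_idx = idx[:400], idx[400:]
    est = PromoterTransformer(preset="tiny", seed=13, max_epochs=12, patience=3)
    est.fit([X[i] for i in train_idx], y[train_idx])
    return est, [X[i] for i in test_idx], y[test_idx], cfg


@pytest.fixture(scope="session")
def permuted_model(planted_sequences):
    """Control classifier fit on label-permuted data; returns (est, X_test, y_test)."""
    _, table = planted_sequences
    X = table["sequence"].tolist()
    y = (table["label"] == "promoter").astype(int).to_numpy()
    rng = np.random.default_rng(99)
    yp = rng.permutation(y)
    est = PromoterTransformer(preset="tiny", seed=13, max_epochs=12, patience=3)
    est.fit(X[:1600], yp[:1600])
    return est, X[1600:], yp[1600:]


from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
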