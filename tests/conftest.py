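"""Shared fixtures: small synthetic datasets and a trained desk-scale model."""

from __future__ import annotations

import numpy as np
import pytest

from pleioscan import cnn, pmca
from pleioscan import synthetic_data as syn


@pytest.fixture(scope="session")
def demo_library() -> pmca.MotifLibrary:
    """Near-deterministic PWMs for the generator's built-in consensi."""
    return pmca.MotifLibrary(
        [pmca.pwm_from_consensus(k, v)
         for k, v in syn.DEMO_MOTIF_CONSENSI.items()],
        {k: k for k in syn.DEMO_MOTIF_CONSENSI})


@pytest.fixture(scope="session")
def peak_fixture():
    """Planted-motif sequence set, small enough for fast training."""
    cfg = syn.SimulationConfig(seed=1, n_pos=600, n_neg=600, seq_length=80,
                               n_disrupting=25, n_neutral=25)
    seqs, labels, offsets, variants = syn.gen_peak_dataset(cfg)
    return cfg, seqs, labels, offsets, variants


@pytest.fixture(scope="session")
def trained_model(peak_fixture):
    """Desk-scale model trained once for the whole session."""
    _, seqs, labels, _, _ = peak_fixture
    ds = cnn.dataset_from_sequences(seqs, labels, seed=1)
    model = cnn.train(ds, cnn.ModelConfig(seed=1, max_epochs=18,
                                          conv_filters=(16, 8),
                                          fc_units=(16,)))
    return ds, model


@pytest.fixture(scope="session")
def epigenome_fixture():
    return syn.gen_epigenome_fixture(syn.SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
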