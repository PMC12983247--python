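"""Shared fixtures: small simulated panels and one trained desk-scale model."""

import numpy as np
import pytest

import menet


@pytest.fixture(scope="session")
def small_panel():
    """3-family panel, 200 samples x 120 markers, additive+family trait."""
    spec = menet.PopulationSpec(n_samples=200, n_markers=120, n_populations=3,
                                divergence=0.15, seed=41)
    gm, labels = menet.simulate_genotypes(spec)
    arch = menet.random_architecture(120, n_additive=10, beta_sd=1.0,
                                     n_epistatic=3, family_variance=0.8,
                                     target_h2=0.7, seed=42)
    phenos = menet.simulate_trait(gm, labels, arch)
    return gm, labels, phenos


@pytest.fixture(scope="session")
def tiny_fit(small_panel):
    """A trained dual-branch model, reused by fusion/attribution/trainer tests."""
    gm, labels, phenos = small_panel
    model = menet.MeNet(
        gm, phenos, labels=labels,
        model_config=menet.ModelConfig(ve_channels=4, embed_dim=32,
                                       pool_len=16, head_hidden=(32, 16)),
        triplet_config=menet.TripletConfig(embed_dim=32, hidden_dim=64))
    res = model.fit(train_config=menet.TrainConfig(seed=7, max_epochs=15,
                                                   early_stop_patience=8),
                    repgeno_epochs=8, seed=7)
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
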