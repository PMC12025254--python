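"""Shared fixtures: small synthetic cohorts and a trained compact model."""

from __future__ import annotations

import numpy as np
import pytest

import duformer as df


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 subjects x 11 s with a strong Gamma effect: 8 recordings."""
    cfg = df.SynthConfig(
        n_subjects=4, duration_s=11.0, effect_band="Gamma", effect_ratio=3.0, seed=7
    )
    return cfg, df.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_gamma_segments(tiny_dataset):
    """Gamma-band epochs of the tiny cohort (80 segments)."""
    _, recordings = tiny_dataset
    pcfg = df.PipelineConfig(bands=(df.get_band("Gamma"),))
    return df.preprocess_dataset(recordings, pcfg)["Gamma"]


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_gamma_segments):
    """A reduced DU-former trained briefly on the tiny Gamma set."""
    model, _ = df.train(
        df.ModelConfig.reduced(seed=3),
        tiny_gamma_segments,
        df.TrainConfig.reduced(seed=3, epochs=20),
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
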