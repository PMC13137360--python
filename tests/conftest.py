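"""Shared fixtures: pipeline config, phantom sets, and one trained classifier.

The trained model is session-scoped because training (even the compact
NumPy network) dominates test runtime; every test that needs a trained
classifier shares the same seeded run, which is itself reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fsdt.config import PipelineConfig
from fsdt.pipeline import phantom_suite, section_training_data, train_sections


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def training_phantoms(pipeline_config):
    """60 balanced phantoms used to fit the shared classifier."""
    return phantom_suite(60, pipeline_config, seed=100)


@pytest.fixture(scope="session")
def trained_model(pipeline_config, training_phantoms):
    """A classifier trained once on the shared phantom set (seed 11)."""
    images, masks, _, _ = training_phantoms
    p_set, q_set, labels = section_training_data(images, masks, pipeline_config)
    model_cfg = dataclasses.replace(pipeline_config.model, seed=11)
    model, record = train_sections(p_set, q_set, labels, model_cfg)
    return model, record


def make_toy_views(n: int = 40, side: int = 20, seed: int = 11):
    """Linearly separable toy sections: bright centered disc vs dark noise.

    Returns (p_set, q_set, labels); the P view of a positive example carries
    a saturated disc, negatives carry only faint noise. Q = 1 - P as in the
    real replication step.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    disc = ((yy - side / 2) ** 2 + (xx - side / 2) ** 2) <= (side / 4) ** 2
    p_set, q_set, labels = [], [], []
    for i in range(n):
        label = i % 2
        base = rng.uniform(0.0, 0.15, size=(side, side))
        if label:
            view = np.where(disc, rng.uniform(0.85, 1.0, size=(side, side)), base)
        else:
            view = base
        p_set.append(view)
        q_set.append(1.0 - view)
        labels.append(label)
    return p_set, q_set, np.array(labels)
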