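"""Shared fixtures: colour models, phantom batches and a cached feature
matrix for the cross-validation tests (expensive, built once per session)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from otomedia import phantoms
from otomedia.core import CLASS_LABELS, FEATURE_NAMES, PipelineConfig, SegmentedImage
from otomedia.vocabulary import extract_features, train_color_model


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def color_models(config):
    """Translucent and amber colour-cluster models trained at the study
    sampling sizes (20 images x 100 pixels, K = 10)."""
    tm = train_color_model(
        phantoms.collect_color_training_pixels("translucent", seed=11),
        n_clusters=config.n_color_clusters,
        label="translucent",
        seed=0,
    )
    am = train_color_model(
        phantoms.collect_color_training_pixels("amber", seed=12),
        n_clusters=config.n_color_clusters,
        label="amber",
        seed=0,
    )
    return tm, am


@pytest.fixture(scope="session")
def separable_features(config, color_models):
    """Eight-feature matrix and labels for 90 separable phantoms (30/class,
    seed 7), extracted with ground-truth masks."""
    tm, am = color_models
    items, _ = phantoms.generate_dataset(30, "separable", seed=7)
    X, y = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for image, truth in items:
            seg = SegmentedImage(image, truth.membrane_mask)
            X.append(extract_features(seg, tm, am, config).as_array())
            y.append(truth.label)
    return np.vstack(X), np.array(y)


def make_feature_table(n_per_class: int, seed: int = 0, separable: bool = True):
    """Synthetic class-conditional feature vectors mimicking the archetype
    feature distributions; with ``separable`` the class supports do not
    overlap on the discriminating features (bulging, malleus, translucency,
    amber)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    spread = 0.0 if separable else 0.3
    for _ in range(n_per_class):
        rows.append([
            rng.uniform(0.25, 0.45), rng.uniform(1.5, 2.5), rng.uniform(1.5, 3.0),
            0.0, rng.uniform(0, 0.05 + spread), rng.uniform(0, 0.05 + spread),
            rng.uniform(0.3, 0.6), rng.uniform(0.01, 0.03),
        ])
        labels.append("AOM")
        rows.append([
            rng.uniform(0, 0.05 + spread / 3), rng.uniform(1.0, 1.7),
            rng.uniform(1.0, 1.8), 0.0, rng.uniform(0, 0.05 + spread),
            rng.uniform(0.9 - spread, 1.0), rng.uniform(0.02, 0.12),
            rng.uniform(0.001, 0.005),
        ])
        labels.append("OME")
        rows.append([
            0.0, rng.uniform(1.0, 1.6), rng.uniform(1.0, 3.0), 1.0,
            rng.uniform(0.9 - spread, 1.0), rng.uniform(0, 0.05 + spread),
            rng.uniform(0.02, 0.08), rng.uniform(0.002, 0.006),
        ])
        labels.append("NOE")
    return np.array(rows), np.array(labels)


@pytest.fixture()
def feature_table():
    return make_feature_table(30, seed=5)


@pytest.fixture(scope="session")
def aom_phantom():
    spec = phantoms.archetype_spec("AOM", seed=0)
    return phantoms.render_phantom(spec)


def segmented(image, truth) -> SegmentedImage:
    return SegmentedImage(image, truth.membrane_mask)
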