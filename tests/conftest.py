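"""Shared fixtures: small synthetic cohorts and a trained toy model."""

import numpy as np
import pytest

from pathcam import (ModelSpec, SyntheticCohortSpec, fit_fold_transforms,
                     generate_cohort, train_model)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact separable cohort used across modules (n=80, P=30)."""
    spec = SyntheticCohortSpec(seed=11, n_samples=80, n_pathways=30,
                               genes_per_pathway=(6, 10), n_omics=2,
                               n_planted=3, effect_size=2.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_images(small_cohort):
    cohort = small_cohort
    idx = np.arange(cohort.annotations.n_samples)
    projections, order, images = fit_fold_transforms(
        cohort.exprs, cohort.pathways, 1, idx)
    return projections, order, images


@pytest.fixture(scope="session")
def small_trained(small_cohort, small_images):
    """An interpretation-style model trained on the whole small cohort."""
    _, _, images = small_images
    spec = ModelSpec(in_channels=2, image_height=30, image_width=1,
                     n_covariates=1, epochs=150, learning_rate=0.01, seed=5)
    return train_model(images, small_cohort.annotations, spec, validation=None)


@pytest.fixture()
def tiny_spec():
    """A spec small enough for finite-difference gradient checks."""
    return ModelSpec(in_channels=2, image_height=8, image_width=2,
                     n_covariates=1, conv_filters=4, dense_units=6,
                     dropout=0.0, seed=0)
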