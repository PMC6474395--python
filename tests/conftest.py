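"""Shared fixtures: tiny studies and float64 networks for exact checks."""

import numpy as np
import pytest

from fmri2img.experiments import StudyConfig, build_study
from fmri2img.models import (ComparatorSpec, DiscriminatorSpec, GeneratorSpec,
                             build_comparator, build_discriminator,
                             build_generator)


@pytest.fixture(scope="session")
def tiny_study():
    """Noiseless 16x16 study: 8 train images x 2 trials, 4 test images, D=64."""
    cfg = StudyConfig(
        n_train_images=8, n_train_trials=2, n_test_natural=4,
        n_test_trials=1, include_shapes=False, include_letters=False,
        canvas_size=16, n_voxels=64, feature_size=8, noise_sd=0.0, seed=11)
    return build_study(cfg)


def tiny_gen_spec(input_dim=6, dtype=np.float64):
    """4-layer generator producing an 8x8 image; small enough for
    exhaustive finite-difference checks."""
    return GeneratorSpec(input_dim=input_dim, fc_widths=[8],
                         seed_channels=4, seed_size=2,
                         upconv=[(4, 4, 2, 1), (3, 4, 2, 1)],
                         output_size=8, dtype=dtype)


def tiny_disc_spec(dtype=np.float64):
    return DiscriminatorSpec(conv=[(4, 3, 2, 1), (6, 3, 2, 1)],
                             fc_widths=[8], dtype=dtype)


def tiny_comp_spec(dtype=np.float64):
    return ComparatorSpec(conv=[(4, 3, 2, 1)],
                          weights_source=("random_fixed", 5), dtype=dtype)


@pytest.fixture
def tiny_nets():
    """float64 generator/discriminator/comparator with kink-free biases."""
    rng = np.random.default_rng(7)
    gen = build_generator(tiny_gen_spec(), rng)
    disc = build_discriminator(tiny_disc_spec(), rng)
    comp = build_comparator(tiny_comp_spec())
    for net in (gen, disc):
        for p in net.params():
            if p.data.ndim == 1:  # keep activations off the ReLU kink
                p.data = p.data + rng.normal(0.0, 0.05, p.data.shape)
    return gen, disc, comp
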