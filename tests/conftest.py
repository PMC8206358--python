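"""Shared fixtures: small seeded phantoms and a tiny trained network.

Everything is generated programmatically; the heavier objects are
session-scoped so the expensive work (phantom rendering, training) runs
once per test session.
"""

from dataclasses import replace

import numpy as np
import pytest

from vista import evaluation as ev
from vista import prediction as pr
from vista import synthetic_data as sd


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic 4-structure phantom without noise, with ground truth."""
    spec = replace(sd.default_phantom_spec(seed=7), field_shape=(8, 96, 96),
                   noise=sd.NOISELESS)
    channels, truth = sd.generate_tissue_phantom(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def cell_phantom():
    """Whole-cell phantom for retention quantification.

    Cells are large compared to the PSF (8 um vs 0.32 um), matching the
    regime of per-cell intensity comparisons where boundary blur is a
    negligible fraction of the mask mass.
    """
    spec = sd.PhantomSpec(
        field_shape=(2, 256, 256), pixel_size_xy=160.0,
        structures=[sd.StructureSpec(sd.StructureKind.NUCLEUS, count=2,
                                     size_nm=8000.0)],
        noise=sd.NOISELESS, seed=9)
    channels, truth = sd.generate_tissue_phantom(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def bead_stack_noiseless():
    """20-bead calibration image: 100 nm beads, 320 nm PSF, 80 nm pixels."""
    vol, truth = sd.generate_bead_stack(diameter=100.0, psf_fwhm=320.0,
                                        pixel_size=80.0, n_beads=20, seed=1)
    return vol, truth


@pytest.fixture(scope="session")
def tiny_identity_model():
    """A small U-Net trained briefly on the identity task (shared)."""
    cfg = pr.TrainConfig.desk_scale(steps=80, patch_size=32, seed=1)
    ds = ev.identity_dataset(n_images=8, side=48, seed=1, config=cfg)
    model = pr.train(ds, cfg)
    return cfg, ds, model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
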