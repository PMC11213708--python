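"""Shared fixtures: small phantoms and patch sets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from flimstain.coregister import (background_mask_from_intensity,
                                  extract_patches)
from flimstain.flim_core import clamp_flim, normalise_intensity
from flimstain.phantom import PhantomSpec, generate_phantom
from flimstain.stain_formats import make_iw_flim


def make_patch_pairs(seeds, size: int = 256, patch: int = 64, limit=None):
    """IW-FLIM / H&E patch pairs from phantom fields (one field per seed)."""
    pairs = []
    for sd in seeds:
        sample = generate_phantom(PhantomSpec(image_size=(size, size), seed=sd))
        field = clamp_flim(sample.flim)
        si = make_iw_flim(field)
        mask = background_mask_from_intensity(normalise_intensity(field))
        pairs += extract_patches(si, sample.he, mask, patch, patch,
                                 field_id=field.field_id)
    return pairs[:limit] if limit else pairs


@pytest.fixture(scope="session")
def phantom_sample():
    return generate_phantom(PhantomSpec(image_size=(256, 256), seed=42))


@pytest.fixture(scope="session")
def clamped_field(phantom_sample):
    return clamp_flim(phantom_sample.flim)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
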