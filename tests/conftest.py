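"""Shared phantom fixtures.

Everything is generated programmatically; the default geometry is the
study protocol (0.9375 mm in plane on a 240 mm FOV, contiguous 4 mm
axial sections) on a desk-scale grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from mslesion import phantom

VOX = (0.9375, 0.9375, 4.0)


def make_lesioned_spec(
    seed: int = 0,
    noise_sigma: float = 0.0,
    grid_shape=(80, 80, 10),
    load_mm3: float = 4000.0,
    deformation_amplitude_mm: float = 0.0,
) -> phantom.PhantomSpec:
    """Phantom spec with randomly placed lesions of all phenotypes."""
    anat = phantom._build_anatomy(grid_shape, VOX, 1.0)
    lesions = phantom.place_lesions(
        anat, VOX, np.random.default_rng(seed), load_mm3, phantom.EffectConfig()
    )
    return phantom.PhantomSpec(
        grid_shape=grid_shape,
        voxel_size=VOX,
        lesion_specs=lesions,
        noise_sigma=noise_sigma,
        deformation_amplitude_mm=deformation_amplitude_mm,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def clean_spec() -> phantom.PhantomSpec:
    return make_lesioned_spec(seed=0)


@pytest.fixture(scope="session")
def clean_study(clean_spec):
    """Noiseless multimodal study: (flair, t1pre, t1post, truth)."""
    return phantom.generate_structural(clean_spec)


@pytest.fixture(scope="session")
def four_type_spec() -> phantom.PhantomSpec:
    """Hand-placed spec with one well-separated lesion per phenotype."""
    lesions = [
        phantom.LesionSpec(center=(20, 40, 2), radius_mm=4.0, true_type="t1_hypointense"),
        phantom.LesionSpec(center=(59, 40, 2), radius_mm=4.0, true_type="active"),
        phantom.LesionSpec(center=(40, 16, 2), radius_mm=4.0, true_type="t1_isointense"),
        phantom.LesionSpec(center=(40, 62, 6), radius_mm=4.5, true_type="ring",
                           ring_thickness_mm=1.5),
    ]
    return phantom.PhantomSpec(grid_shape=(80, 80, 10), voxel_size=VOX,
                               lesion_specs=lesions, rng_seed=1)


@pytest.fixture(scope="session")
def four_type_study(four_type_spec):
    return phantom.generate_structural(four_type_spec)
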