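import numpy as np
import pytest

from fibrilmorph import (SegmentationParams, SyntheticImageSpec,
                         generate_fibril_image, measure, segment)
from fibrilmorph.distributions import MixtureParams

NM_PER_PX = 4.0
FIELD_PX = 1024


def single_population(mean=150.0, sd=20.0):
    return MixtureParams([mean], [sd**2], [1.0])


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free RSA field of 200 non-touching disks plus its ground truth."""
    spec = SyntheticImageSpec(
        width_px=FIELD_PX, height_px=FIELD_PX, nm_per_px=NM_PER_PX,
        diameter_mixture=single_population(), min_gap_nm=30.0,
        target_count=200, noise_sd=0.0, seed=1)
    image, truth = generate_fibril_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_field_segmented(clean_field):
    spec, image, truth = clean_field
    labels, ac = segment(image, SegmentationParams(), spec.nm_per_px)
    return spec, image, truth, labels, ac


@pytest.fixture(scope="session")
def clean_field_records(clean_field_segmented):
    spec, image, truth, labels, ac = clean_field_segmented
    return spec, truth, labels, measure(labels, spec.nm_per_px)


def rasterize_disk(shape, cx, cy, radius):
    """Reference rasteriser: pixel in disk iff its centre is (px units)."""
    rows = np.arange(shape[0]) + 0.5
    cols = np.arange(shape[1]) + 0.5
    return ((rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2) <= radius**2
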