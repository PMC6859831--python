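import numpy as np
import pytest

from octaquant.images import EnFaceImage
from octaquant.synthetic import CohortConfig, generate_cohort


def make_image(pixels, extent_mm=6.0, slab_kind="CC"):
    return EnFaceImage(pixels=np.asarray(pixels, dtype=float),
                       extent_mm=extent_mm, slab_kind=slab_kind)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject image cohort at reduced grid, moderate index spread."""
    cfg = CohortConfig(
        n_subjects=3, grid_px=128, max_shift_px=4, seed=42,
        mean_index=0.2, between_subject_sd=0.05, within_subject_sd=0.01,
        noise_sd=5.0,
    )
    return generate_cohort(cfg)
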