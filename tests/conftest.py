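import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cinecompare as cc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def desk_config() -> cc.PhantomConfig:
    """The default desk-scale phantom (64x64, N=8, S=8)."""
    return cc.PhantomConfig()


@pytest.fixture(scope="session")
def small_config() -> cc.PhantomConfig:
    """A minimal phantom for fast structural tests (16x16, N=4, S=4)."""
    return cc.PhantomConfig(
        image_size=16,
        pixel_spacing=24.0,
        slice_thickness=10.0,
        n_couch=4,
        slices_per_couch=4,
    )


@pytest.fixture(scope="session")
def default_pair(desk_config) -> cc.phantom.ValidationPair:
    """One corrupted/corrected sorting pair at the default study conditions."""
    return cc.make_validation_pair(desk_config, n_missed_peaks=3, n_spurious_peaks=1, seed=1)


def random_imageset(
    n_phases=2, n_couch=3, slices_per_couch=2, shape=(6, 6), seed=0, times=False
) -> cc.FourDCTImageSet:
    """A small image set of seeded random HU slices (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    pixels = rng.uniform(-1000, 1000, (n_phases, n_couch, slices_per_couch, *shape))
    t = None
    if times:
        t = np.arange(n_phases * n_couch * slices_per_couch, dtype=float).reshape(
            n_phases, n_couch, slices_per_couch
        )
    return cc.imageset_from_array(pixels, range(0, 10 * n_phases, 10), times=t)
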