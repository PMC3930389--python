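import numpy as np
import pytest

from tumorperf import PhantomSpec, TumorGeometry


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Compact phantom: elliptical rim/core tumor plus kidney disc on a 24x32 slice."""
    return PhantomSpec(
        grid_shape=(24, 32),
        tumor=TumorGeometry(center=(12.0, 12.0), rim_radii=(7.0, 8.0), core_radii=(3.0, 4.0)),
        kidney_center=(12.0, 25.0),
        kidney_radius=3.0,
        seed=7,
    )


@pytest.fixture
def noise_free_spec(small_spec) -> PhantomSpec:
    from dataclasses import replace

    return replace(small_spec, noise_sd=0.0)


@pytest.fixture
def vessel_spec() -> PhantomSpec:
    """Larger tumor with room to pack several synthetic vessels."""
    return PhantomSpec(
        grid_shape=(32, 44),
        tumor=TumorGeometry(center=(16.0, 16.0), rim_radii=(11.0, 12.0), core_radii=(4.0, 5.0)),
        kidney_center=(16.0, 36.0),
        kidney_radius=4.0,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
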