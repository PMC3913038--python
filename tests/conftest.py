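import numpy as np
import pytest

from ldbridges.synthetic_data import FieldSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_field_spec():
    """A quick-to-render field with well-separated bright disks."""
    return FieldSpec(
        field_width_um=25.6,
        field_height_um=25.6,
        pixel_size_um=0.1,
        n_ld=12,
        ld_radius_law={"kind": "fixed", "radius_um": 0.8},
        n_foci=15,
        focus_radius_um=0.2,
        enrichment=0.0,
        noise_sd=5.0,
        seed=7,
    )
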