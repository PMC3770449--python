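import numpy as np
import pytest

from intomics.data import PlatformData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_platform(
    values,
    group=None,
    platform_id="p1",
    subject_id=None,
    dtype="continuous",
    biomarker_ids=None,
):
    values = np.asarray(values, dtype=float)
    if group is None:
        half = values.shape[1] // 2
        group = ["control"] * half + ["disease"] * (values.shape[1] - half)
    return PlatformData(
        platform_id=platform_id,
        values=values,
        group=np.asarray(group, dtype=object),
        biomarker_ids=biomarker_ids,
        subject_id=subject_id,
        dtype=dtype,
    )


@pytest.fixture
def two_noise_platforms(rng):
    """Two unlinked platforms of pure noise, 20 biomarkers, 5+5 samples."""
    return [
        make_platform(rng.standard_normal((20, 10)), platform_id="p1"),
        make_platform(rng.standard_normal((20, 10)), platform_id="p2"),
    ]
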