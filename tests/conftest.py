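import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bgaudit import SyntheticSpec, generate_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220)


@pytest.fixture(scope="session")
def small_spec():
    """A quick-to-render dataset spec with the default class contrast."""
    return SyntheticSpec(
        image_height=64,
        image_width=64,
        n_per_class=12,
        cell_radius_range=(9, 14),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


def random_density(rng, n_bins, full_support=False):
    """A random normalized density vector."""
    raw = rng.gamma(0.8, size=n_bins)
    if full_support:
        raw += 1e-3
    else:
        raw[rng.random(n_bins) < 0.3] = 0.0
        if raw.sum() == 0:
            raw[rng.integers(n_bins)] = 1.0
    return raw / raw.sum()
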