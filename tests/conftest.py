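import numpy as np
import pytest

from margincad.phantom import DeficitRegion, PhantomSpec, generate_cohort


def small_spec(noise_sigma: float = 2.0, factors: dict | None = None,
               seed: int = 0) -> PhantomSpec:
    """A scaled-down phantom (30×24×26) for fast unit tests."""
    if factors is None:
        factors = {"AD1": 0.85, "AD2": 0.75, "AD3": 0.60}
    return PhantomSpec(
        shape=(30, 24, 26),
        brain_center=(14.5, 11.5, 12.5),
        brain_semi_axes=(12.0, 9.5, 10.5),
        deficit_regions=[
            DeficitRegion(center=(9.0, 11.5, 12.5), semi_axes=(3.5, 4.0, 4.0),
                          severity_factors=dict(factors)),
            DeficitRegion(center=(20.0, 11.5, 12.5), semi_axes=(3.5, 4.0, 4.0),
                          severity_factors=dict(factors)),
        ],
        baseline_intensity=100.0,
        noise_sigma=noise_sigma,
        smoothing_fwhm_vox=2.0,
        subject_gain_sigma=0.1,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 CTRL + 12 AD small-phantom cohort with planted deficits."""
    records, truth = generate_cohort(small_spec(), 12, 12, seed=7)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
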