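import numpy as np
import pytest

from thermoparam import CohortSpec, HeatSourceTruth, forward_temperature_point, synth_cohort
from thermoparam.segmentation import RoIProfile

PIXEL_SIZE = 0.0006  # metres, the default object-plane pixel
H0 = 8.77
TE = 22.0


def make_noiseless_profile(d: float, peak_elevation: float, n_offsets: int = 31) -> RoIProfile:
    """Radial profile sampled exactly from the point-source forward model."""
    q = peak_elevation * 4.0 * np.pi * H0 * d**2
    src = HeatSourceTruth((0, 0), d, q, te=TE, h0=H0)
    offsets = np.arange(n_offsets) * PIXEL_SIZE
    temps = forward_temperature_point(offsets, src)
    return RoIProfile(
        offsets=offsets,
        mean_temp=temps,
        tmax=float(temps[0]),
        hotspot=(0, 0),
        te=TE,
        n_directions=np.full(n_offsets, 4),
    )


@pytest.fixture(scope="session")
def noiseless_profile():
    return make_noiseless_profile(d=0.01, peak_elevation=12.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12 normal / 10 abnormal cohort for fast pipeline tests."""
    spec = CohortSpec(n_normal=12, n_abnormal=10, seed=11)
    thermograms, mask, truth = synth_cohort(spec)
    return spec, thermograms, mask, truth
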