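import numpy as np
import pytest

from qmripd.dce import Aif
from qmripd.phantom import (
    AcquisitionSpec,
    NoiseSpec,
    PhantomSpec,
    RegionSpec,
    TissueTruth,
    TreatmentEffect,
    population_aif,
)


def small_regions():
    """Compact regions for a 16x16x4 grid to keep fits fast."""
    het = {"adc": 0.05, "t1": 0.05, "ktrans": 0.1, "ve": 0.1, "vp": 0.1, "m0": 0.03}
    return [
        RegionSpec("tumor", (4.5, 4.5, 1.5), (3.0, 3.0, 1.4),
                   TissueTruth(adc=1.6e-3, t1=1.0, ktrans=0.12, ve=0.35, vp=0.03),
                   heterogeneity_sd=het, name="tumor1"),
        RegionSpec("tumor", (11.5, 4.5, 1.5), (2.6, 2.6, 1.4),
                   TissueTruth(adc=1.1e-3, t1=0.7, ktrans=0.25, ve=0.5, vp=0.05),
                   heterogeneity_sd=het, name="tumor2"),
        RegionSpec("reference", (4.5, 11.5, 1.5), (2.6, 2.6, 1.4),
                   TissueTruth(adc=1.0e-3, t1=0.58, ktrans=0.1, ve=0.3, vp=0.02),
                   name="reference"),
        RegionSpec("artery", (12.5, 12.5, 1.5), (1.4, 1.4, 1.8),
                   TissueTruth(adc=3.0e-3, t1=1.4, ktrans=0.0, ve=0.1, vp=0.5),
                   name="artery"),
    ]


@pytest.fixture
def small_spec():
    return PhantomSpec(
        grid_shape=(16, 16, 4),
        regions=small_regions(),
        visits=("baseline", "day1"),
        effect=TreatmentEffect(
            multipliers={"adc": 0.7, "t1": 0.6, "ktrans": 2.2, "ve": 1.4, "vp": 1.6},
            decay={"day1": 1.0},
        ),
        noise=NoiseSpec(sigma_rel=0.0),
        acquisition=AcquisitionSpec(dce_n_frames=48),
        seed=7,
    )


@pytest.fixture
def times48():
    return np.arange(48) * 8.0


@pytest.fixture
def aif48(times48) -> Aif:
    aif = population_aif(times48, injection_time=64.0)
    aif.arrival_frame = 8
    return aif
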