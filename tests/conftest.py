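import datetime as dt

import numpy as np
import pytest

from brachyverify import (CoefficientQuad, DwellGeometry, DwellPosition,
                          KermaCalibration, SourceSpec, load_source_spec)


@pytest.fixture(scope="session")
def gammamed():
    """Built-in GammaMed Plus HDR Ir-192 source model."""
    return load_source_spec("GammaMedPlus-Ir192")


@pytest.fixture(scope="session")
def flat_source():
    """Degenerate source with g_L == 1 and F == 1 everywhere.

    Isolates the geometry factor in dose computations.
    """
    zero = CoefficientQuad()
    one = CoefficientQuad(c4=1.0)
    return SourceSpec(
        name="flat", active_length_L=0.35, dose_rate_constant_Lambda=1.0,
        half_life=73.83, radial_h=1.0, radial_i=0.0, radial_j=0.0, radial_k=1.0,
        aniso_k=one, aniso_a=zero, aniso_b=zero, aniso_e=zero,
        aniso_a_prime=zero, aniso_b_prime=zero, aniso_e_prime=zero)


@pytest.fixture
def axial_dwell():
    """Single dwell at the origin, axis along +z."""
    return DwellGeometry(center=np.zeros(3), orientation=np.array([0.0, 0.0, 1.0]))


@pytest.fixture
def calibration():
    return KermaCalibration(Sk_calibration=40700.0,
                            calibration_date=dt.date(2022, 4, 1),
                            treatment_date=dt.date(2022, 4, 15))


def make_dwells(centers, times, orientation=(0.0, 0.0, 1.0), channel="1"):
    orientation = np.asarray(orientation, float)
    return [
        DwellPosition(index=i, channel=channel, dwell_time=float(t),
                      geometry=DwellGeometry(center=np.asarray(c, float),
                                             orientation=orientation))
        for i, (c, t) in enumerate(zip(centers, times))
    ]
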