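import math

import numpy as np
import pytest

from hydrasense import BleachGeometry, CalibrationPoint, build_calibration
from hydrasense.frap_sim import single_component_d_of_rh


def soumpasis_series_oracle(t: float, tau_d: float) -> float:
    """Independent high-precision evaluation of the disk-bleach recovery
    fraction via plain Taylor series of the modified Bessel functions.

    Valid for moderate arguments (2 tau_d / t <~ 40); used only as a test
    oracle, never by the implementation.
    """
    x = 2.0 * tau_d / t
    half = x / 2.0
    term0, term1 = 1.0, half  # k = 0 terms of I0 and I1
    i0_terms, i1_terms = [term0], [term1]
    for k in range(1, 200):
        term0 *= half * half / (k * k)
        term1 *= half * half / (k * (k + 1))
        i0_terms.append(term0)
        i1_terms.append(term1)
        if term0 < 1e-30 and term1 < 1e-30:
            break
    return math.exp(-x) * (math.fsum(i0_terms) + math.fsum(i1_terms))


@pytest.fixture
def geometry() -> BleachGeometry:
    return BleachGeometry()  # 10 um spot, 50 um field, 0.5 s interval


@pytest.fixture
def single_component_curve():
    """Calibration curve through the canonical single-component D(RH)
    profile, one replicate per knot."""
    points = [CalibrationPoint(rh, (d,)) for rh, d in single_component_d_of_rh()]
    return build_calibration(points)


@pytest.fixture
def frame_times(geometry):
    return (np.arange(100) + 0.5) * geometry.frame_interval
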