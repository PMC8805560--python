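import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sonocell import MembraneParams, UltrasoundBurst, HHParams


@pytest.fixture
def water_membrane() -> MembraneParams:
    """10 um anchor span, 1 mN/m surface tension, water properties."""
    return MembraneParams(d=10.0e-6, gamma=1.0e-3)


@pytest.fixture
def burst_7mhz() -> UltrasoundBurst:
    """1 MPa, 7 MHz, 5 ms burst starting at t = 0."""
    return UltrasoundBurst(P0=1.0e6, f=7.0e6, t_dur=5.0e-3)


@pytest.fixture
def hh_defaults() -> HHParams:
    return HHParams()
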