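import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nmrpeakfit.spectrum_io import AxisCalibration


@pytest.fixture
def small_axes() -> tuple[AxisCalibration, AxisCalibration]:
    """A compact 15N-1H axis pair keeping synthetic grids small."""
    f1 = AxisCalibration(n_points=64, spectral_width=1350.0, observe_freq=60.8,
                         carrier_ppm=118.0, label="15N")
    f2 = AxisCalibration(n_points=128, spectral_width=2000.0, observe_freq=600.0,
                         carrier_ppm=8.3, label="1H")
    return f1, f2
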