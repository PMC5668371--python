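import numpy as np
import pytest

from v1aging.spikes import StimulusProtocol
from v1aging.tuning import TuningCurve, double_gaussian

DIRECTIONS = np.arange(0.0, 360.0, 15.0)


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


def noiseless_curve(a0, a1, a2, theta0, sigma, sa=1.0) -> TuningCurve:
    """A 24-direction tuning curve sampled from the double-Gaussian model."""
    y = double_gaussian(DIRECTIONS, a0, a1, a2, theta0, sigma)
    return TuningCurve(
        directions_deg=DIRECTIONS.copy(),
        mean_response=np.asarray(y, dtype=float),
        sd_response=np.zeros_like(DIRECTIONS),
        sa=sa,
    )
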