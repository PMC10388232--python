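import numpy as np
import pytest

from gaitdtw.gait_model import GaitProfileParams
from gaitdtw.signal_io import ForceSignal


@pytest.fixture
def params():
    """Default gait parameters (700 N subject, 100 Hz, 1 s stance)."""
    return GaitProfileParams()


@pytest.fixture
def noiseless_params():
    """Deterministic generator: no sensor noise, quantization kept on."""
    return GaitProfileParams(noise_sd=0.0)


@pytest.fixture
def make_signal():
    """Factory for simple uniformly sampled test signals."""

    def _make(force, sample_rate=100.0, gap_mask=None, **kw):
        force = np.asarray(force, dtype=float)
        return ForceSignal(
            time=np.arange(len(force)) / sample_rate,
            force=force,
            gap_mask=gap_mask,
            sample_rate=sample_rate,
            **kw,
        )

    return _make
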