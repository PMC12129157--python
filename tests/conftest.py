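import logging

import numpy as np
import pytest

# CLI tests rebind logging to the runner's captured stderr; once that buffer
# closes, later library log calls would print spurious handleError noise.
logging.raiseExceptions = False

from vocog import AudioClip, MockEncoder

SR = 16000
WIN = 5 * SR


def tone(freq: float, dur_s: float = 5.0, sr: int = SR, amp: float = 0.3) -> AudioClip:
    t = np.arange(int(dur_s * sr)) / sr
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), sr)


@pytest.fixture(scope="session")
def tone_window():
    return tone


@pytest.fixture(scope="session")
def mock_encoder():
    return MockEncoder(seed=0)
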