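"""Audio reading, writing and standardization.

Every downstream stage of the screening pipeline assumes the canonical
format used here: 16-bit, 16 kHz, mono, amplitudes in [-1, 1].  This
module converts arbitrary PCM/float WAV input to that format, applies
RMS volume normalization (so recording level cannot leak into the
features), and offers an optional spectral-gating denoiser.

The pipeline contract is single-speaker audio: recordings containing an
examiner's voice must be separated upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

logger = logging.getLogger("vocog")

CANONICAL_RATE = 16_000
#: amplitude quantum of the 16-bit grid
Q16 = 1.0 / 32768.0


class AudioFormatError(ValueError):
    """Raised for non-WAV input or unsupported codecs."""


class AudioValidationError(ValueError):
    """Raised when a clip violates an operation's precondition."""


@dataclass
class AudioClip:
    """A mono waveform with amplitudes in [-1, 1].

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes.
    sample_rate : int
        Sampling rate in Hz (canonical: 16000).
    """

    samples: np.ndarray
    sample_rate: int
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()

    @property
    def duration_s(self) -> float:
        """Clip length in seconds (sample count / rate)."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


_INT_SCALES = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: str | Path) -> AudioClip:
    """Read a RIFF/WAV file into an :class:`AudioClip`.

    Integer PCM (8/16/24/32-bit) is scaled to [-1, 1]; float data is
    passed through.  Stereo or multi-channel audio is mixed down to mono
    by channel averaging.  The file's original sample rate is preserved
    (use :func:`standardize` to resample).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"cannot decode {path}: {exc}") from exc
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_SCALES:
        x = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise AudioFormatError(
            f"unsupported WAV sample encoding {data.dtype} in {path}"
        )
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioClip(np.clip(x, -1.0, 1.0), int(rate), source=str(path))


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM little-endian WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32768.0).clip(-32768, 32767).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate, pcm)


def standardize(clip: AudioClip, rate: int = CANONICAL_RATE) -> AudioClip:
    """Convert a clip to the canonical 16-bit / 16 kHz / mono format.

    Resampling uses polyphase filtering (:func:`scipy.signal.resample_poly`
    with its default Kaiser window), which is deterministic across runs.
    Amplitudes are then snapped to the 16-bit grid, so a second call is
    the identity.
    """
    if len(clip) == 0:
        raise AudioValidationError("cannot standardize an empty clip")
    x = clip.samples
    if clip.sample_rate != rate:
        g = math.gcd(rate, clip.sample_rate)
        x = resample_poly(x, rate // g, clip.sample_rate // g)
    x = np.clip(x, -1.0, 1.0 - Q16)
    x = np.round(x / Q16) * Q16  # 16-bit quantization grid
    return AudioClip(x, rate, source=clip.source)


def rms_dbfs(samples: np.ndarray) -> float:
    """RMS level in dB relative to full scale; -inf for silence."""
    rms = float(np.sqrt(np.mean(np.square(samples))))
    if rms == 0.0:
        return -math.inf
    return 20.0 * math.log10(rms)


def rms_normalize(clip: AudioClip, target_dbfs: float = -20.0) -> AudioClip:
    """Scale a clip to a target RMS level (default -20 dBFS).

    An all-zero clip is returned unchanged with a warning.  If the gain
    would push samples past full scale, the clip is peak-limited (scaled
    so the peak sits at 1) and a warning is logged; the resulting RMS is
    then below target, which is the correct trade-off for a screening
    feature pipeline — clipping distortion is worse than level error.
    """
    level = rms_dbfs(clip.samples)
    if level == -math.inf:
        logger.warning("rms_normalize: all-zero clip %s left unchanged", clip.source)
        return AudioClip(clip.samples.copy(), clip.sample_rate, source=clip.source)
    gain = 10.0 ** ((target_dbfs - level) / 20.0)
    x = clip.samples * gain
    peak = float(np.max(np.abs(x)))
    if peak > 1.0:
        logger.warning(
            "rms_normalize: peak limiting %s (peak %.2f after gain)", clip.source, peak
        )
        x = x / peak
    return AudioClip(x, clip.sample_rate, source=clip.source)


# ---------------------------------------------------------------------------
# Spectral-gating denoiser
# ---------------------------------------------------------------------------

_DENOISE_NFFT = 512
_DENOISE_HOP = 128
#: a bin is "noise" when its magnitude is below profile × this factor
_GATE_FACTOR = 1.5


def _stft(x: np.ndarray, nfft: int, hop: int) -> np.ndarray:
    win = get_window("hann", nfft)
    n_frames = 1 + (len(x) - nfft) // hop
    idx = np.arange(nfft)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.fft.rfft(x[idx] * win, axis=1)


def _istft(spec: np.ndarray, nfft: int, hop: int, n_out: int) -> np.ndarray:
    win = get_window("hann", nfft)
    frames = np.fft.irfft(spec, n=nfft, axis=1) * win
    out = np.zeros(n_out + nfft)
    norm = np.zeros(n_out + nfft)
    w2 = win * win
    for i in range(frames.shape[0]):
        out[i * hop : i * hop + nfft] += frames[i]
        norm[i * hop : i * hop + nfft] += w2
    # interior window-squared sum is 1.5 (hann, 4x overlap); clamping the
    # taper edges avoids amplifying rounding noise there
    norm = np.maximum(norm, 0.1)
    return (out / norm)[:n_out]


def denoise(clip: AudioClip, strength: float = 0.5) -> AudioClip:
    """Attenuate stationary background noise by spectral gating.

    The noise magnitude profile is estimated per frequency bin from the
    lowest-energy 10% of analysis frames; bins falling below
    profile × gate factor are attenuated by ``strength`` (0 = identity,
    1 = full gate).  Output length equals input length.
    """
    if not 0.0 <= strength <= 1.0:
        raise AudioValidationError("denoise strength must lie in [0, 1]")
    if strength == 0.0:
        return AudioClip(clip.samples.copy(), clip.sample_rate, source=clip.source)
    if len(clip) < _DENOISE_NFFT:
        raise AudioValidationError(
            f"clip shorter than one analysis frame ({_DENOISE_NFFT} samples)"
        )
    n = len(clip)
    x = np.pad(clip.samples, (0, _DENOISE_NFFT))  # cover the tail
    spec = _stft(x, _DENOISE_NFFT, _DENOISE_HOP)
    mag = np.abs(spec)
    frame_energy = np.sum(mag**2, axis=1)
    k = max(1, int(0.10 * len(frame_energy)))
    quiet = np.argsort(frame_energy)[:k]
    profile = mag[quiet].mean(axis=0)  # per-bin noise floor
    # median-filter across frequency: narrowband signal components that
    # leak into the quiet frames must not inflate their own floor
    from scipy.signal import medfilt

    profile = medfilt(profile, kernel_size=9)
    gated = mag < profile[None, :] * _GATE_FACTOR
    gain = np.where(gated, 1.0 - strength, 1.0)
    y = _istft(spec * gain, _DENOISE_NFFT, _DENOISE_HOP, n)
    return AudioClip(np.clip(y, -1.0, 1.0), clip.sample_rate, source=clip.source)
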