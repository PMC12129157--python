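"""Reading, standardization, level normalization and denoising."""

import numpy as np
import pytest
from scipy.io import wavfile

from vocog import (
    AudioClip,
    AudioValidationError,
    denoise,
    read_wav,
    rms_normalize,
    standardize,
    write_wav,
)
from vocog.audio_io import rms_dbfs

from conftest import SR, tone


def test_read_stereo_mixes_to_mono(tmp_path):
    rng = np.random.default_rng(0)
    stereo = (rng.uniform(-0.5, 0.5, size=(88200, 2)) * 32767).astype(np.int16)
    p = tmp_path / "stereo.wav"
    wavfile.write(p, 44100, stereo)
    clip = read_wav(p)
    assert len(clip) == 88200
    assert clip.sample_rate == 44100
    expected = stereo.astype(np.float64).mean(axis=1) / 32768.0
    np.testing.assert_allclose(clip.samples, expected, atol=1e-12)


def test_read_zero_and_fullscale(tmp_path):
    p = tmp_path / "z.wav"
    wavfile.write(p, SR, np.zeros(100, dtype=np.int16))
    assert np.all(read_wav(p).samples == 0.0)
    p2 = tmp_path / "f.wav"
    wavfile.write(p2, SR, np.full(100, 32767, dtype=np.int16))
    assert np.all(np.abs(read_wav(p2).samples - 1.0) <= 1 / 32768)


def test_read_write_roundtrip_bit_exact(tmp_path):
    rng = np.random.default_rng(1)
    pcm = rng.integers(-32768, 32768, size=16000).astype(np.int16)
    clip = AudioClip(pcm / 32768.0, SR)
    p = tmp_path / "rt.wav"
    write_wav(p, clip)
    back = read_wav(p)
    np.testing.assert_array_equal(back.samples, clip.samples)


def test_read_missing_and_bad_format(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_wav(tmp_path / "nope.wav")
    bad = tmp_path / "bad.wav"
    bad.write_bytes(b"not a riff file at all")
    with pytest.raises(ValueError):
        read_wav(bad)


def test_standardize_resamples_8k_to_16k():
    clip = tone(200, dur_s=2.0, sr=8000)
    out = standardize(clip)
    assert out.sample_rate == 16000
    assert len(out) == 32000
    assert abs(out.duration_s - 2.0) < 1 / 16000


def test_standardize_idempotent():
    clip = tone(300, dur_s=1.0)
    once = standardize(clip)
    twice = standardize(once)
    np.testing.assert_array_equal(once.samples, twice.samples)


def test_standardize_preserves_tone_frequency():
    clip = tone(440, dur_s=2.0, sr=48000)
    out = standardize(clip)
    spec = np.abs(np.fft.rfft(out.samples))
    freqs = np.fft.rfftfreq(len(out), d=1 / 16000)
    peak = freqs[np.argmax(spec)]
    assert abs(peak - 440.0) <= freqs[1]  # within one FFT bin


def test_standardize_empty_rejected():
    with pytest.raises(AudioValidationError):
        standardize(AudioClip(np.array([]), 16000))


def test_rms_normalize_hits_target():
    clip = tone(250, amp=10 ** (-30 / 20) * np.sqrt(2))  # about -30 dBFS RMS
    out = rms_normalize(clip, target_dbfs=-20.0)
    assert abs(rms_dbfs(out.samples) + 20.0) < 0.1


@pytest.mark.parametrize("alpha", [0.1, 0.5, 2.0])
def test_rms_normalize_gain_invariant(alpha):
    base = tone(250, amp=0.1)
    scaled = AudioClip(np.clip(alpha * base.samples, -1, 1), SR)
    a = rms_normalize(base).samples
    b = rms_normalize(scaled).samples
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_rms_normalize_zero_clip_unchanged():
    clip = AudioClip(np.zeros(1000), SR)
    out = rms_normalize(clip)
    assert np.all(out.samples == 0.0)


def test_rms_normalize_peak_limits():
    # a sparse spike: RMS is far below peak, gain would clip
    x = np.zeros(16000)
    x[::4000] = 0.5
    out = rms_normalize(AudioClip(x, SR), target_dbfs=-10.0)
    assert np.max(np.abs(out.samples)) <= 1.0


def test_denoise_improves_snr():
    rng = np.random.default_rng(2)
    sig = tone(220, dur_s=3.0).samples
    noise = rng.standard_normal(len(sig)) * np.sqrt(np.mean(sig**2))  # 0 dB SNR
    noisy = AudioClip(np.clip(sig + noise, -1, 1), SR)

    def snr(x):
        err = x - sig
        return 10 * np.log10(np.mean(sig**2) / np.mean(err**2))

    out = denoise(noisy, strength=0.8)
    assert snr(out.samples) > snr(noisy.samples)


def test_denoise_identity_at_zero_strength():
    clip = tone(330, dur_s=1.0)
    out = denoise(clip, strength=0.0)
    np.testing.assert_array_equal(out.samples, clip.samples)


def test_denoise_silence_stays_silent():
    clip = AudioClip(np.zeros(16000), SR)
    out = denoise(clip, strength=0.7)
    assert len(out) == len(clip)
    assert np.max(np.abs(out.samples)) < 1e-10


def test_denoise_short_clip_rejected():
    with pytest.raises(AudioValidationError):
        denoise(AudioClip(np.zeros(100), SR), strength=0.5)
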