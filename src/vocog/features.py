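"""Windowing and traditional acoustic feature extraction.

A standardized clip is cut into 5-second windows with a 1-second
overlap (hop 4 s).  From each window three feature streams are
extracted:

* voicing probability, 100 frames (50-ms hop) — low values mark the
  silent intervals that are the strongest prosodic marker of decline;
* fundamental frequency (F0), the same 100-frame grid, in Hz, zeroed
  on unvoiced frames;
* an aggregated MFCC vector: 20 coefficients × {max, mean, mean of
  first-order delta} = 60 values.

Together with a 768-dimensional window embedding these concatenate to
the 1028-value per-window vector consumed by the classifier.

The F0/voicing estimator is a YIN-type algorithm: the cumulative-mean
normalized difference function (CMNDF) is evaluated over the pitch
search range, the first dip below an aperiodicity threshold gives the
period, and the depth of that dip (combined with a frame-energy gate)
is mapped to a voicing probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

from .audio_io import CANONICAL_RATE, AudioClip, AudioValidationError

logger = logging.getLogger("vocog")

WINDOW_S = 5.0
HOP_S = 4.0  # window minus the 1-s overlap
FRAME_HOP_S = 0.05
N_FRAMES = 100  # frames per window: WINDOW_S / FRAME_HOP_S
EMBED_DIM = 768
MFCC_AGG_DIM = 60
STEP_DIM = EMBED_DIM + 2 * N_FRAMES + MFCC_AGG_DIM  # 1028

#: column layout of a feature step
LAYOUT = {
    "embedding": slice(0, 768),
    "voiced_prob": slice(768, 868),
    "f0": slice(868, 968),
    "mfcc_agg": slice(968, 1028),
}


@dataclass
class SegmentGrid:
    """Start times of the 5-s analysis windows of one clip."""

    window_s: float
    hop_s: float
    starts: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class FrameTrack:
    """A per-frame scalar track (100 frames per 5-s window)."""

    values: np.ndarray
    frame_hop_s: float = FRAME_HOP_S

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass
class MfccConfig:
    """Geometry of the MFCC analysis.

    20 coefficients aggregated as max/mean/delta-mean give the
    60-value per-window vector.  ``delta_agg`` selects how the
    first-order delta track is reduced (mean is the default).
    """

    n_mfcc: int = 20
    frame_length_s: float = 0.025
    frame_hop_s: float = 0.010
    n_fft: int = 512
    n_mels: int = 40
    fmin: float = 20.0
    fmax: float = 8000.0
    delta_agg: str = "mean"  # mean | max


@dataclass
class F0Config:
    """Pitch search range and voicing decision parameters."""

    fmin: float = 60.0
    fmax: float = 400.0
    frame_length: int = 1024  # samples of the YIN analysis frame
    aperiodicity_threshold: float = 0.15
    voicing_cutoff: float = 0.5
    interpolate_unvoiced: bool = False  # linear interp instead of zeros


@dataclass
class FeatureSequence:
    """Time-ordered (T × 1028) feature matrix for one clip."""

    steps: np.ndarray
    clip_id: str = ""
    starts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.steps = np.atleast_2d(np.asarray(self.steps, dtype=np.float64))
        if self.steps.shape[1] != STEP_DIM:
            raise AudioValidationError(
                f"feature steps must have {STEP_DIM} values, got {self.steps.shape[1]}"
            )

    def __len__(self) -> int:
        return self.steps.shape[0]


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def make_segments(
    clip: AudioClip, pad: bool = False
) -> tuple[SegmentGrid, list[AudioClip]]:
    """Cut a standardized clip into 5-s windows at 4-s hops.

    Window starts are 0, 4, 8, … s while the full window fits inside
    the clip; trailing audio shorter than a window is discarded (with a
    log message).  ``pad=True`` zero-pads a clip shorter than one
    window up to 5 s instead of rejecting it.
    """
    if clip.sample_rate != CANONICAL_RATE:
        raise AudioValidationError(
            f"windowing expects a standardized {CANONICAL_RATE} Hz clip, "
            f"got {clip.sample_rate} Hz"
        )
    win = int(round(WINDOW_S * clip.sample_rate))
    hop = int(round(HOP_S * clip.sample_rate))
    x = clip.samples
    if len(x) < win:
        if not pad:
            raise AudioValidationError(
                f"clip is {clip.duration_s:.2f} s, shorter than the {WINDOW_S:.0f}-s "
                "analysis window; zero-pad short clips with --pad"
            )
        x = np.pad(x, (0, win - len(x)))
    n_win = (len(x) - win) // hop + 1
    starts = HOP_S * np.arange(n_win)
    leftover = len(x) - ((n_win - 1) * hop + win)
    if leftover > 0:
        logger.info(
            "discarding %.2f s of trailing audio (< one full window)",
            leftover / clip.sample_rate,
        )
    windows = [
        AudioClip(x[i * hop : i * hop + win], clip.sample_rate, source=clip.source)
        for i in range(n_win)
    ]
    return SegmentGrid(WINDOW_S, HOP_S, starts), windows


def _check_window(window: AudioClip) -> np.ndarray:
    n = int(round(WINDOW_S * CANONICAL_RATE))
    if window.sample_rate != CANONICAL_RATE or len(window) != n:
        raise AudioValidationError(
            f"expected a {WINDOW_S:.0f}-s window of {n} samples at "
            f"{CANONICAL_RATE} Hz, got {len(window)} at {window.sample_rate}"
        )
    return window.samples


# ---------------------------------------------------------------------------
# F0 and voicing probability (YIN-type)
# ---------------------------------------------------------------------------

def _cmndf(frames: np.ndarray, w: int, max_lag: int) -> np.ndarray:
    """Cumulative-mean normalized difference function per frame.

    ``frames`` has shape (n_frames, w + max_lag); returns
    (n_frames, max_lag + 1) with value 1 at lag 0.
    """
    n = 1 << int(np.ceil(np.log2(frames.shape[1] * 2)))
    spec = np.fft.rfft(frames, n=n, axis=1)
    head = np.fft.rfft(frames[:, :w], n=n, axis=1)
    corr = np.fft.irfft(np.conj(head) * spec, n=n, axis=1)[:, : max_lag + 1]
    sq = np.cumsum(frames**2, axis=1)
    r0 = sq[:, w - 1]
    lags = np.arange(max_lag + 1)
    r_tau = sq[:, lags + w - 1] - np.concatenate(
        [np.zeros((len(frames), 1)), sq[:, lags[1:] - 1]], axis=1
    )
    diff = np.maximum(r0[:, None] + r_tau - 2.0 * corr, 0.0)
    cum = np.cumsum(diff[:, 1:], axis=1)
    cmndf = np.ones_like(diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        cmndf[:, 1:] = diff[:, 1:] * lags[1:] / np.where(cum > 0, cum, 1.0)
    cmndf[:, 1:][cum <= 0] = 1.0
    return cmndf


def extract_f0_voicing(
    window: AudioClip, cfg: F0Config | None = None
) -> tuple[FrameTrack, FrameTrack]:
    """Estimate per-frame F0 (Hz) and voicing probability for a 5-s window.

    Returns two 100-frame tracks on a 50-ms hop.  F0 is set to exactly
    0 on frames whose voicing probability falls below the cutoff
    (or linearly interpolated across them if the config requests it).
    """
    cfg = cfg or F0Config()
    x = _check_window(window)
    sr = CANONICAL_RATE
    hop = int(round(FRAME_HOP_S * sr))
    w = cfg.frame_length
    tau_min = max(2, int(sr / cfg.fmax))
    tau_max = int(np.ceil(sr / cfg.fmin))
    seg_len = w + tau_max

    centers = hop // 2 + hop * np.arange(N_FRAMES)
    pad = seg_len  # generous zero padding at both ends
    xp = np.pad(x, (pad, pad))
    idx = (centers[:, None] - w // 2 + pad) + np.arange(seg_len)[None, :]
    frames = xp[idx]

    cmndf = _cmndf(frames, w, tau_max)

    # first dip below the aperiodicity threshold, else the global min
    region = cmndf[:, tau_min : tau_max + 1]
    below = region < cfg.aperiodicity_threshold
    first = np.argmax(below, axis=1)
    has_dip = below.any(axis=1)
    best = np.where(has_dip, first, np.argmin(region, axis=1)) + tau_min
    # walk each dip down to its local minimum
    for i in range(len(best)):
        t = best[i]
        while t + 1 <= tau_max and cmndf[i, t + 1] < cmndf[i, t]:
            t += 1
        best[i] = t

    # parabolic interpolation of the minimum for sub-sample period accuracy
    t = best
    tm = np.clip(t - 1, 0, tau_max)
    tp = np.clip(t + 1, 0, tau_max)
    rows = np.arange(len(t))
    a, b, c = cmndf[rows, tm], cmndf[rows, t], cmndf[rows, tp]
    denom = a - 2 * b + c
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / np.where(denom == 0, 1, denom), 0.0)
    period = t + np.clip(shift, -0.5, 0.5)
    f0 = sr / period
    dip = cmndf[rows, t]

    # voicing probability: dip depth gated by frame energy
    frame_rms = np.sqrt(np.mean(frames[:, :w] ** 2, axis=1))
    energy_gate = 1.0 / (1.0 + np.exp(-(np.log10(frame_rms + 1e-12) + 3.0) * 6.0))
    voiced_prob = np.clip(1.0 - dip, 0.0, 1.0) * energy_gate

    voiced = voiced_prob >= cfg.voicing_cutoff
    f0 = np.where(voiced, np.clip(f0, cfg.fmin, cfg.fmax), 0.0)
    if cfg.interpolate_unvoiced and voiced.any() and not voiced.all():
        pos = np.arange(N_FRAMES)
        f0 = np.interp(pos, pos[voiced], f0[voiced])
    return FrameTrack(f0), FrameTrack(voiced_prob)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sr: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    fb = np.zeros((n_mels, len(bins)))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i : i + 3]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    # area normalization keeps filter output comparable across bands
    enorm = 2.0 / (hz_pts[2:] - hz_pts[:-2])
    return fb * enorm[:, None]


def log_mel_spectrogram(
    x: np.ndarray,
    sr: int = CANONICAL_RATE,
    n_fft: int = 512,
    frame_length: int = 400,
    hop: int = 160,
    n_mels: int = 40,
    fmin: float = 20.0,
    fmax: float = 8000.0,
    rel_floor: float | None = None,
) -> np.ndarray:
    """Log mel power spectrogram, shape (n_frames, n_mels).

    ``rel_floor`` floors the mel power relative to the spectrogram's
    maximum instead of absolutely, which makes the log output shift by
    an exact constant under global gain (used by the mock encoder's
    gain-invariance contract).
    """
    n_frames = 1 + (len(x) - frame_length) // hop
    if n_frames < 1:
        raise AudioValidationError("signal shorter than one MFCC analysis frame")
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    win = np.hanning(frame_length)
    spec = np.abs(np.fft.rfft(x[idx] * win, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_mels, n_fft, sr, fmin, fmax)
    mel = spec @ fb.T
    if rel_floor is not None:
        floor = max(float(mel.max()) * rel_floor, 1e-300)
    else:
        floor = 1e-10
    return np.log(np.maximum(mel, floor))


def mfcc(window_samples: np.ndarray, cfg: MfccConfig) -> np.ndarray:
    """Per-frame MFCC matrix, shape (n_frames, n_mfcc)."""
    sr = CANONICAL_RATE
    logmel = log_mel_spectrogram(
        window_samples,
        sr=sr,
        n_fft=cfg.n_fft,
        frame_length=int(round(cfg.frame_length_s * sr)),
        hop=int(round(cfg.frame_hop_s * sr)),
        n_mels=cfg.n_mels,
        fmin=cfg.fmin,
        fmax=cfg.fmax,
    )
    return dct(logmel, type=2, norm="ortho", axis=1)[:, : cfg.n_mfcc]


def extract_mfcc_agg(window: AudioClip, cfg: MfccConfig | None = None) -> np.ndarray:
    """Aggregate window MFCCs to the fixed 60-value vector.

    Layout: [per-coefficient max (20) | mean (20) | delta aggregate (20)],
    where delta is the frame-to-frame first difference.
    """
    cfg = cfg or MfccConfig()
    x = _check_window(window)
    m = mfcc(x, cfg)
    delta = np.diff(m, axis=0)
    if cfg.delta_agg == "max":
        dagg = delta.max(axis=0)
    else:
        dagg = delta.mean(axis=0)
    return np.concatenate([m.max(axis=0), m.mean(axis=0), dagg])


# ---------------------------------------------------------------------------
# Full per-clip sequence
# ---------------------------------------------------------------------------

def extract_sequence(
    clip: AudioClip,
    encoder,
    mfcc_cfg: MfccConfig | None = None,
    f0_cfg: F0Config | None = None,
    pad: bool = False,
    clip_id: str = "",
) -> FeatureSequence:
    """Run the full per-window extraction and stack the T × 1028 sequence.

    Column layout per step: [embedding 768 | voicing 100 | F0 100 |
    MFCC aggregate 60] (see :data:`LAYOUT`).
    """
    grid, windows = make_segments(clip, pad=pad)
    steps = np.empty((len(windows), STEP_DIM))
    for i, w in enumerate(windows):
        emb = encoder.embed(w)
        f0, vp = extract_f0_voicing(w, f0_cfg)
        agg = extract_mfcc_agg(w, mfcc_cfg)
        steps[i] = np.concatenate([emb.values, vp.values, f0.values, agg])
    return FeatureSequence(steps, clip_id=clip_id or clip.source, starts=grid.starts)


def save_sequence(path, seq: FeatureSequence, meta: dict | None = None) -> None:
    """Write a feature sequence as a compressed array with a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, steps=seq.steps, starts=seq.starts)
    layout = {k: [v.start, v.stop] for k, v in LAYOUT.items()}
    sidecar = {"clip_id": seq.clip_id, "layout": layout, **(meta or {})}
    side_path = path.with_suffix(path.suffix + ".json") if path.suffix == ".npz" else Path(str(path) + ".json")
    side_path.write_text(json.dumps(sidecar, indent=2))


def load_sequence(path) -> FeatureSequence:
    from pathlib import Path

    path = Path(path)
    with np.load(path) as z:
        return FeatureSequence(z["steps"], clip_id=path.stem, starts=z["starts"])
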