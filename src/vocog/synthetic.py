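"""Synthetic speech-like audio with controllable CN/CD prosody.

Real patient audio for this task is private, so the package ships a
source-filter style generator that emulates the prosodic phenotype the
clinical literature associates with cognitive decline: a slower
syllable rate, a larger fraction of time spent in pauses, longer
individual pauses, and reduced pitch variability.  Utterances are
built as alternating bursts of harmonic "syllables" (per-syllable F0
drawn from a normal distribution, vowel-like spectral envelope, raised
cosine amplitude contour) and silences whose durations are tuned so
the long-run silent fraction matches the requested pause ratio.

No claim of phonetic realism is made: there is no lexical content, no
speaker identity, and no examiner's voice.  The generator exists so the
full pipeline — features, training, evaluation — can be exercised and
its statistical behaviour tested without any private data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .audio_io import CANONICAL_RATE, AudioClip, write_wav


class SynthesisError(ValueError):
    """Raised for infeasible phenotype parameter combinations."""


@dataclass
class PhenotypeParams:
    """Prosodic control parameters of one speaker class.

    syllable_rate is in syllables per second of speaking time;
    pause_ratio is the long-run fraction of the clip that is silent.
    """

    syllable_rate: float = 4.0
    pause_ratio: float = 0.20
    mean_pause_s: float = 0.4
    f0_mean: float = 180.0
    f0_sd: float = 30.0
    amp_jitter: float = 0.1

    def validate(self) -> None:
        if not (0.0 < self.pause_ratio < 0.9):
            raise SynthesisError(f"pause_ratio must lie in (0, 0.9), got {self.pause_ratio}")
        for name in ("syllable_rate", "mean_pause_s", "f0_mean", "f0_sd"):
            if getattr(self, name) <= 0:
                raise SynthesisError(f"{name} must be positive")
        burst_s = self.mean_pause_s * (1 - self.pause_ratio) / self.pause_ratio
        if burst_s * self.syllable_rate < 0.5:
            raise SynthesisError(
                "infeasible combination: the pause ratio and mean pause length "
                "leave no room for even one syllable per burst"
            )


#: default cognitively-normal phenotype
CN_PARAMS = PhenotypeParams(
    syllable_rate=4.0, pause_ratio=0.20, mean_pause_s=0.4, f0_mean=180.0, f0_sd=30.0
)
#: default cognitively-declined phenotype: slower, longer pauses, flatter pitch
CD_PARAMS = PhenotypeParams(
    syllable_rate=2.5, pause_ratio=0.45, mean_pause_s=1.2, f0_mean=180.0, f0_sd=10.0
)


@dataclass
class CorpusSpec:
    n_per_class: int = 40
    duration_s: float = 60.0
    seed: int = 7
    cn_params: PhenotypeParams = field(default_factory=lambda: replace(CN_PARAMS))
    cd_params: PhenotypeParams = field(default_factory=lambda: replace(CD_PARAMS))


def narrow_gap_spec(gap: float, **kwargs) -> CorpusSpec:
    """A corpus whose CD phenotype is pulled toward CN by factor (1 - gap).

    ``gap=1`` reproduces the default separation, ``gap=0`` makes the
    classes identically distributed.
    """
    cn, cd = CN_PARAMS, CD_PARAMS
    mix = {
        f: getattr(cn, f) + gap * (getattr(cd, f) - getattr(cn, f))
        for f in ("syllable_rate", "pause_ratio", "mean_pause_s", "f0_mean", "f0_sd")
    }
    return CorpusSpec(cd_params=PhenotypeParams(**mix), **kwargs)


_SYLLABLE_TAPER_S = 0.020
_NOISE_FLOOR = 1e-4
_FORMANTS = ((500.0, 150.0, 2.0), (1500.0, 300.0, 1.0), (2500.0, 400.0, 0.3))


def _syllable(f0: float, dur_s: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """One vowel-like harmonic syllable with raised cosine edges."""
    sr = CANONICAL_RATE
    n = max(1, int(round(dur_s * sr)))
    t = np.arange(n) / sr
    x = np.zeros(n)
    k = 1
    while k * f0 < 4000.0:
        fk = k * f0
        g = 1.0 / k
        for fc, bw, height in _FORMANTS:
            g += (height / k) * np.exp(-(((fk - fc) / bw) ** 2))
        phase = rng.uniform(0, 2 * np.pi)
        x += g * np.sin(2 * np.pi * fk * t + phase)
        k += 1
    x /= np.max(np.abs(x)) + 1e-12
    taper = min(int(_SYLLABLE_TAPER_S * sr), n // 2)
    env = np.ones(n)
    if taper > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(taper) / taper))
        env[:taper] = ramp
        env[-taper:] = ramp[::-1]
    return amp * env * x


def synth_utterance(
    params: PhenotypeParams, duration_s: float = 60.0, seed: int = 0
) -> AudioClip:
    """Generate one deterministic speech-like clip of exact duration.

    Bursts of contiguous syllables alternate with gamma-distributed
    pauses; expected burst length is chosen so the long-run silent
    fraction equals ``params.pause_ratio``.
    """
    if duration_s < 5.0:
        raise SynthesisError("utterances must be at least 5 s (one analysis window)")
    params.validate()
    rng = np.random.default_rng(seed)
    sr = CANONICAL_RATE
    n_total = int(round(duration_s * sr))
    syl_dur = 1.0 / params.syllable_rate
    burst_s = params.mean_pause_s * (1 - params.pause_ratio) / params.pause_ratio
    mean_syll = burst_s / syl_dur

    pieces: list[np.ndarray] = []
    n_done = 0
    silent_n = 0
    # open with a partial pause so clips don't all start identically
    first = int(rng.uniform(0, params.mean_pause_s) * sr)
    pieces.append(np.zeros(first))
    n_done += first
    silent_n += first
    r = params.pause_ratio
    while n_done < n_total:
        # burst length steers the cumulative silent fraction back to the
        # target, so even a single 60-s clip realizes pause_ratio tightly
        speech_n = n_done - silent_n
        target_burst_s = max(silent_n * (1 - r) / r - speech_n, 0.0) / sr
        n_syll = int(round(rng.normal(target_burst_s / syl_dur, 0.2 * mean_syll)))
        n_syll = int(np.clip(n_syll, 1, np.ceil(3 * mean_syll)))
        for _ in range(n_syll):
            f0 = float(np.clip(rng.normal(params.f0_mean, params.f0_sd), 75.0, 380.0))
            dur = syl_dur * float(rng.lognormal(0.0, 0.08))
            amp = 0.3 * max(0.05, 1.0 + params.amp_jitter * rng.normal())
            pieces.append(_syllable(f0, dur, amp, rng))
            n_done += len(pieces[-1])
        pause = float(rng.gamma(4.0, params.mean_pause_s / 4.0))
        n_pause = int(round(max(0.08, pause) * sr))
        pieces.append(np.zeros(n_pause))
        n_done += n_pause
        silent_n += n_pause
    x = np.concatenate(pieces)[:n_total]
    if len(x) < n_total:
        x = np.pad(x, (0, n_total - len(x)))
    x = x + _NOISE_FLOOR * rng.standard_normal(n_total)  # faint room tone
    return AudioClip(np.clip(x, -1.0, 1.0), sr)


_CD_DIAGNOSES = ("AD", "AD", "AD", "DLB", "VaD")  # rough prevalence mix
_CN_DIAGNOSES = ("SCD", "MCI", "MCI")


def generate_corpus(spec: CorpusSpec) -> list[tuple[AudioClip, dict]]:
    """Generate the labeled corpus in memory.

    Returns (clip, row) pairs where ``row`` matches the manifest schema.
    CD clips receive a synthetic MMSE drawn uniformly from 10-23 and CN
    clips from 24-30, so the labeling rule is genuinely exercised; the
    score is metadata glue, not an acoustic claim.
    """
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * spec.n_per_class)]
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for cls, params, tag in ((0, spec.cn_params, "cn"), (1, spec.cd_params, "cd")):
        params.validate()
        for i in range(spec.n_per_class):
            seed = child_seeds[cls * spec.n_per_class + i]
            clip = synth_utterance(params, spec.duration_s, seed=seed)
            mmse = int(meta_rng.integers(24, 31)) if cls == 0 else int(meta_rng.integers(10, 24))
            dx_pool = _CN_DIAGNOSES if cls == 0 else _CD_DIAGNOSES
            row = {
                "subject_id": f"{tag}{i:03d}",
                "wav_path": f"{tag}{i:03d}.wav",
                "mmse": mmse,
                "diagnosis": dx_pool[int(meta_rng.integers(len(dx_pool)))],
            }
            out.append((clip, row))
    return out


def synth_corpus(spec: CorpusSpec, out_dir: str | Path, force: bool = False) -> Path:
    """Write the corpus as WAV files + manifest.csv + params.json.

    Refuses to write into an existing non-empty directory unless
    ``force`` is set.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass --force to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for clip, row in generate_corpus(spec):
        write_wav(out_dir / row["wav_path"], clip)
        rows.append(row)
    import pandas as pd

    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    provenance = {
        "seed": spec.seed,
        "n_per_class": spec.n_per_class,
        "duration_s": spec.duration_s,
        "cn_params": asdict(spec.cn_params),
        "cd_params": asdict(spec.cd_params),
    }
    (out_dir / "params.json").write_text(json.dumps(provenance, indent=2))
    return manifest
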