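"""End-to-end glue: audio → features → classifier → screening metrics.

These helpers chain the modules in the order the method runs and are
what the command-line interface and the reproducibility script call.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import audio_io
from .encoder import MockEncoder
from .evaluation import evaluate, roc_auc
from .features import F0Config, FeatureSequence, MfccConfig, extract_sequence
from .labeling import label_from_mmse
from .model import CognitiveVoiceClassifier, ModelConfig, TrainConfig, build_model, train
from .synthetic import CorpusSpec, generate_corpus

logger = logging.getLogger("vocog")


def featurize_clip(
    clip: audio_io.AudioClip,
    encoder,
    denoise_strength: float = 0.0,
    target_dbfs: float = -20.0,
    mfcc_cfg: MfccConfig | None = None,
    f0_cfg: F0Config | None = None,
    pad: bool = False,
    clip_id: str = "",
) -> FeatureSequence:
    """Standardize, level-normalize, optionally denoise, then extract."""
    clip = audio_io.standardize(clip)
    clip = audio_io.rms_normalize(clip, target_dbfs=target_dbfs)
    if denoise_strength > 0:
        clip = audio_io.denoise(clip, strength=denoise_strength)
    return extract_sequence(clip, encoder, mfcc_cfg=mfcc_cfg, f0_cfg=f0_cfg, pad=pad, clip_id=clip_id)


def featurize_wav(path: str | Path, encoder, **kwargs) -> FeatureSequence:
    clip = audio_io.read_wav(path)
    return featurize_clip(clip, encoder, clip_id=str(path), **kwargs)


def run_synthetic_experiment(
    n_train: int = 40,
    n_test: int = 10,
    seed: int = 7,
    duration_s: float = 60.0,
    epochs: int = 50,
    permute_labels: bool = False,
    spec: CorpusSpec | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict:
    """Train on a synthetic corpus and score the held-out clips.

    Generates ``n_train + n_test`` clips per class in memory (CN and CD
    default phenotypes unless a spec overrides them), extracts features
    with the mock encoder, trains the classifier, and reports held-out
    AUC plus the thresholded screening metrics.  ``permute_labels``
    shuffles the training labels — the permutation-null control whose
    held-out AUC should hover near chance.
    """
    spec = spec or CorpusSpec(n_per_class=n_train + n_test, duration_s=duration_s, seed=seed)
    enc = MockEncoder(seed=seed)
    corpus = generate_corpus(spec)

    logger.info("featurizing %d synthetic clips", len(corpus))
    feats: list[tuple[FeatureSequence, int]] = []
    for clip, row in corpus:
        seq = featurize_clip(clip, enc, clip_id=row["subject_id"])
        feats.append((seq, label_from_mmse(row["mmse"])))

    per_class = spec.n_per_class
    cn = feats[:per_class]
    cd = feats[per_class:]
    train_set = cn[:n_train] + cd[:n_train]
    test_set = cn[n_train : n_train + n_test] + cd[n_train : n_train + n_test]

    train_labels = [y for _, y in train_set]
    if permute_labels:
        rng = np.random.default_rng(seed + 1)
        train_labels = list(rng.permutation(train_labels))
        train_set = [(s, y) for (s, _), y in zip(train_set, train_labels)]

    model = build_model(model_cfg, seed=seed)
    tcfg = train_cfg or TrainConfig(epochs=epochs, seed=seed)
    model, history = train(model, train_set, tcfg)

    pairs = [(model.predict_proba(s), y) for s, y in test_set]
    auc, _ = roc_auc(pairs)
    report = evaluate(pairs)
    return {
        "model": model,
        "history": history,
        "test_pairs": pairs,
        "auc": auc,
        "report": report,
    }


def load_labeled_features(records, encoder, audio_root: str | Path = ".", **kwargs):
    """Featurize every manifest record; returns [(FeatureSequence, label)]."""
    audio_root = Path(audio_root)
    out = []
    for rec in records:
        p = Path(rec.wav_path)
        if not p.is_absolute():
            p = audio_root / p
        seq = featurize_wav(p, encoder, **kwargs)
        seq.clip_id = rec.subject_id
        out.append((seq, rec.label))
    return out
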