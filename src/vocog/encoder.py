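"""Pluggable 768-dimensional window embeddings.

The classifier consumes one 768-value embedding per 5-s window,
alongside the traditional acoustic streams.  Two encoders provide it:

* :class:`MockEncoder` (default) — a seeded fixed random projection of
  gain-normalized log-mel statistics.  It is deterministic, needs no
  downloads, and exists to make the pipeline trainable and testable;
  it makes no claim to representation quality.
* :class:`HubertEncoder` — an adapter for a pre-trained self-supervised
  speech model, mean- or max-pooling the last hidden layer's frame
  outputs over the window.  Requires the optional ``hubert`` extra.

Swapping encoders changes values and provenance only, never shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioClip
from .features import EMBED_DIM, log_mel_spectrogram


@dataclass
class EmbeddingVector:
    """A 768-value window embedding with encoder provenance."""

    values: np.ndarray
    encoder_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != EMBED_DIM:
            raise ValueError(f"embedding must have {EMBED_DIM} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite values")


class MockEncoder:
    """Seeded random projection of pooled log-mel features to 768 dims.

    The window's log-mel spectrogram is pooled over frames (mean and
    standard deviation per mel band), centred so a global gain change —
    an additive constant in the log domain — cancels, then passed
    through a fixed Gaussian projection with a tanh squash.  Identical
    windows map to bit-identical embeddings.
    """

    def __init__(self, seed: int = 0, pooling: str = "mean", n_mels: int = 64):
        if pooling not in ("mean", "max"):
            raise ValueError("pooling must be 'mean' or 'max'")
        self.seed = seed
        self.pooling = pooling
        self.n_mels = n_mels
        rng = np.random.default_rng(seed)
        self._w = rng.standard_normal((EMBED_DIM, 2 * n_mels)) / np.sqrt(2 * n_mels)
        self._b = rng.standard_normal(EMBED_DIM) * 0.1
        self.encoder_id = f"mock-seed{seed}-{pooling}"

    def embed(self, window: AudioClip) -> EmbeddingVector:
        logmel = log_mel_spectrogram(window.samples, n_mels=self.n_mels, rel_floor=1e-8)
        # additive gain offset cancels after per-window centring
        logmel = logmel - logmel.mean()
        if self.pooling == "mean":
            pooled_a = logmel.mean(axis=0)
        else:
            pooled_a = logmel.max(axis=0)
        pooled_b = logmel.std(axis=0)
        feats = np.concatenate([pooled_a, pooled_b])
        return EmbeddingVector(np.tanh(self._w @ feats + self._b), self.encoder_id)


class HubertEncoder:
    """Adapter for a pre-trained self-supervised speech encoder.

    Loads a HuBERT-base checkpoint through ``transformers`` and pools
    the final hidden layer's frame vectors over the window.  The model
    weights are not shipped with this package.
    """

    def __init__(self, model_name: str = "rinna/japanese-hubert-base", pooling: str = "mean"):
        if pooling not in ("mean", "max"):
            raise ValueError("pooling must be 'mean' or 'max'")
        try:
            import torch  # noqa: F401
            from transformers import AutoModel
        except ImportError as exc:
            raise RuntimeError(
                "the pretrained speech encoder needs the optional 'hubert' extra "
                "(pip install vocog[hubert]); use --encoder mock for a "
                "dependency-free run"
            ) from exc
        self.pooling = pooling
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.encoder_id = model_name

    def embed(self, window: AudioClip) -> EmbeddingVector:
        import torch

        with torch.no_grad():
            x = torch.as_tensor(window.samples, dtype=torch.float32)[None, :]
            hidden = self._model(x).last_hidden_state[0]  # (frames, 768)
            pooled = hidden.mean(dim=0) if self.pooling == "mean" else hidden.max(dim=0).values
        return EmbeddingVector(pooled.numpy().astype(np.float64), self.encoder_id)


def get_encoder(name: str = "mock", seed: int = 0, pooling: str = "mean"):
    """Construct an encoder by config name (``mock`` or ``hubert``)."""
    if name == "mock":
        return MockEncoder(seed=seed, pooling=pooling)
    if name == "hubert":
        return HubertEncoder(pooling=pooling)
    raise ValueError(f"unknown encoder '{name}' (expected mock or hubert)")
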