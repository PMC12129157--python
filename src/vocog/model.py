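"""The dementia-screening sequence classifier.

Architecture, applied to the (T × 1028) per-clip feature sequence:

1. a per-time-step fully connected stack (1028 → 1128 → 768, ReLU),
2. a two-layer bidirectional LSTM with 512 hidden units per direction,
3. the final forward and backward hidden states concatenated (1024)
   and passed through a classification head (1024 → 1024 → 512 → 1),
4. a sigmoid giving the probability that the clip's speaker is
   cognitively declined (CD); probability ≥ 0.5 decides CD.

Implemented directly on numpy: dense forward/backward passes,
backpropagation through time, Adam updates, binary cross-entropy loss.
Training fits a per-dimension standardizer on the training features
(stored in the checkpoint) so the heterogeneous streams — F0 in Hz,
voicing probabilities in [0, 1], MFCCs — enter the network on a common
scale; the feature files themselves stay raw.

All randomness is owned by explicit seeds; a fixed seed reproduces the
training trajectory bit-for-bit on one machine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .features import STEP_DIM, FeatureSequence

logger = logging.getLogger("vocog")

CD_THRESHOLD = 0.5


@dataclass
class ModelConfig:
    fc_pre: tuple[int, ...] = (1128, 768)
    lstm_hidden: int = 512
    lstm_layers: int = 2
    fc_head: tuple[int, ...] = (1024, 512)
    input_dim: int = STEP_DIM

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["fc_pre"] = tuple(d["fc_pre"])
        d["fc_head"] = tuple(d["fc_head"])
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization settings (binary cross-entropy + Adam)."""

    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    val_fraction: float = 0.2
    patience: int = 10  # epochs without val improvement before stopping
    clip_norm: float = 5.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Prediction:
    """Model output probability plus the thresholded decision."""

    probability: float
    threshold: float = CD_THRESHOLD

    @property
    def decision(self) -> str:
        return "CD" if self.probability >= self.threshold else "CN"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out)).astype(np.float32)


class CognitiveVoiceClassifier:
    """FC → Bi-LSTM → FC binary classifier over feature sequences."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self.scaler_mean = np.zeros(self.cfg.input_dim, dtype=np.float32)
        self.scaler_std = np.ones(self.cfg.input_dim, dtype=np.float32)
        self._init_params(np.random.default_rng(seed))

    # -- construction -------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.cfg
        p = self.params
        d = c.input_dim
        for i, width in enumerate(c.fc_pre):
            p[f"pre{i}_W"] = _glorot(rng, d, width)
            p[f"pre{i}_b"] = np.zeros(width, dtype=np.float32)
            d = width
        h = c.lstm_hidden
        for layer in range(c.lstm_layers):
            for dirn in ("f", "b"):
                p[f"lstm{layer}{dirn}_Wx"] = _glorot(rng, d, 4 * h)
                p[f"lstm{layer}{dirn}_Wh"] = _glorot(rng, h, 4 * h)
                bias = np.zeros(4 * h, dtype=np.float32)
                bias[h : 2 * h] = 1.0  # forget-gate bias
                p[f"lstm{layer}{dirn}_b"] = bias
            d = 2 * h
        for i, width in enumerate(c.fc_head):
            p[f"head{i}_W"] = _glorot(rng, d, width)
            p[f"head{i}_b"] = np.zeros(width, dtype=np.float32)
            d = width
        p["out_W"] = _glorot(rng, d, 1)
        p["out_b"] = np.zeros(1, dtype=np.float32)

    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ------------------------------------------------------------

    def _lstm_dir(self, X: np.ndarray, key: str, reverse: bool):
        """One LSTM direction over X (B, T, D); returns (H_seq, cache)."""
        p = self.params
        Wx, Wh, b = p[key + "_Wx"], p[key + "_Wh"], p[key + "_b"]
        B, T, _ = X.shape
        H = Wh.shape[0]
        order = range(T - 1, -1, -1) if reverse else range(T)
        h = np.zeros((B, H), dtype=np.float32)
        cstate = np.zeros((B, H), dtype=np.float32)
        H_seq = np.zeros((B, T, H), dtype=np.float32)
        steps = []
        XW = X @ Wx  # precompute input contribution for all steps
        for t in order:
            z = XW[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = cstate, h
            cstate = f * c_prev + i * g
            tc = np.tanh(cstate)
            h = o * tc
            H_seq[:, t] = h
            steps.append((t, i, f, g, o, c_prev, h_prev, tc))
        return H_seq, (key, X, steps, reverse)

    def _lstm_dir_backward(self, cache, dH_seq: np.ndarray, grads: dict):
        key, X, steps, _ = cache
        p = self.params
        Wx, Wh = p[key + "_Wx"], p[key + "_Wh"]
        B, T, D = X.shape
        H = Wh.shape[0]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(p[key + "_b"])
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H), dtype=np.float32)
        dc_next = np.zeros((B, H), dtype=np.float32)
        for t, i, f, g, o, c_prev, h_prev, tc in reversed(steps):
            dh = dH_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] += dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        grads[key + "_Wx"] = grads.get(key + "_Wx", 0) + dWx
        grads[key + "_Wh"] = grads.get(key + "_Wh", 0) + dWh
        grads[key + "_b"] = grads.get(key + "_b", 0) + db
        return dX

    def _forward(self, X: np.ndarray):
        """Forward pass on a batch (B, T, input_dim) of scaled features."""
        p = self.params
        c = self.cfg
        cache: dict = {"pre": []}
        A = X
        for i in range(len(c.fc_pre)):
            Z = A @ p[f"pre{i}_W"] + p[f"pre{i}_b"]
            A_new = np.maximum(Z, 0.0)
            cache["pre"].append((A, Z > 0))
            A = A_new
        cache["lstm"] = []
        for layer in range(c.lstm_layers):
            Hf, cf = self._lstm_dir(A, f"lstm{layer}f", reverse=False)
            Hb, cb = self._lstm_dir(A, f"lstm{layer}b", reverse=True)
            cache["lstm"].append((cf, cb))
            A = np.concatenate([Hf, Hb], axis=2)
        # final states: forward direction at last step, backward at first
        final = np.concatenate([A[:, -1, : c.lstm_hidden], A[:, 0, c.lstm_hidden :]], axis=1)
        cache["final_in"] = A
        a = final
        cache["head"] = []
        for i in range(len(c.fc_head)):
            z = a @ p[f"head{i}_W"] + p[f"head{i}_b"]
            a_new = np.maximum(z, 0.0)
            cache["head"].append((a, z > 0))
            a = a_new
        logit = (a @ p["out_W"] + p["out_b"]).ravel()
        cache["out_in"] = a
        prob = _sigmoid(logit)
        cache["prob"] = prob
        return prob, cache

    def _backward(self, cache, dlogit: np.ndarray) -> dict:
        p = self.params
        c = self.cfg
        grads: dict = {}
        a = cache["out_in"]
        grads["out_W"] = a.T @ dlogit[:, None]
        grads["out_b"] = dlogit.sum(keepdims=True)
        da = dlogit[:, None] @ p["out_W"].T
        for i in range(len(c.fc_head) - 1, -1, -1):
            a_in, mask = cache["head"][i]
            dz = da * mask
            grads[f"head{i}_W"] = a_in.T @ dz
            grads[f"head{i}_b"] = dz.sum(axis=0)
            da = dz @ p[f"head{i}_W"].T
        # route final-state gradient back into the top LSTM layer's outputs
        A_top = cache["final_in"]
        H = c.lstm_hidden
        dA = np.zeros_like(A_top)
        dA[:, -1, :H] = da[:, :H]
        dA[:, 0, H:] = da[:, H:]
        for layer in range(c.lstm_layers - 1, -1, -1):
            cf, cb = cache["lstm"][layer]
            dXf = self._lstm_dir_backward(cf, dA[:, :, :H], grads)
            dXb = self._lstm_dir_backward(cb, dA[:, :, H:], grads)
            dA = dXf + dXb
        for i in range(len(c.fc_pre) - 1, -1, -1):
            A_in, mask = cache["pre"][i]
            dZ = dA * mask
            B, T, _ = dZ.shape
            grads[f"pre{i}_W"] = A_in.reshape(B * T, -1).T @ dZ.reshape(B * T, -1)
            grads[f"pre{i}_b"] = dZ.sum(axis=(0, 1))
            dA = dZ @ p[f"pre{i}_W"].T
        return grads

    # -- inference ----------------------------------------------------------

    def _scale(self, steps: np.ndarray) -> np.ndarray:
        return ((steps - self.scaler_mean) / self.scaler_std).astype(np.float32)

    def predict_proba(self, seq: FeatureSequence) -> float:
        X = self._scale(seq.steps)[None, :, :]
        prob, _ = self._forward(X)
        return float(prob[0])

    # -- persistence --------------------------------------------------------

    def save(self, path, train_cfg: TrainConfig | None = None, extra: dict | None = None) -> None:
        """Single-file checkpoint: weights + configs + scaler + seed."""
        meta = {
            "model_config": self.cfg.to_dict(),
            "seed": self.seed,
            "train_config": train_cfg.to_dict() if train_cfg else None,
            "feature_layout": f"embedding768|voiced100|f0100|mfcc60:dim{self.cfg.input_dim}",
            **(extra or {}),
        }
        np.savez_compressed(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            scaler_mean=self.scaler_mean,
            scaler_std=self.scaler_std,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "CognitiveVoiceClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(ModelConfig.from_dict(meta["model_config"]), seed=meta["seed"])
            for k in model.params:
                model.params[k] = z[k]
            model.scaler_mean = z["scaler_mean"]
            model.scaler_std = z["scaler_std"]
        return model


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> CognitiveVoiceClassifier:
    """Construct a classifier with seeded initial parameters."""
    cfg = cfg or ModelConfig()
    if cfg.input_dim <= 0:
        raise ValueError("input_dim must be positive")
    return CognitiveVoiceClassifier(cfg, seed=seed)


def predict(model: CognitiveVoiceClassifier, seq: FeatureSequence) -> Prediction:
    """Probability of cognitive decline for one clip, thresholded at 0.5."""
    return Prediction(model.predict_proba(seq))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(prob, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def _batches_by_length(idx: np.ndarray, lengths: np.ndarray, batch_size: int):
    """Yield equal-length batches (sequences are stacked, not padded)."""
    by_len: dict[int, list[int]] = {}
    for i in idx:
        by_len.setdefault(int(lengths[i]), []).append(int(i))
    for _, members in sorted(by_len.items()):
        for k in range(0, len(members), batch_size):
            yield members[k : k + batch_size]


def train(
    model: CognitiveVoiceClassifier,
    dataset: list[tuple[FeatureSequence, int]],
    cfg: TrainConfig | None = None,
) -> tuple[CognitiveVoiceClassifier, list[dict]]:
    """Fit the classifier; returns the best-validation-loss model + history.

    The feature standardizer is fitted on the training split only.
    Validation is a stratified hold-out; the parameters with the lowest
    validation loss across epochs are restored before returning.
    """
    cfg = cfg or TrainConfig()
    labels = np.array([int(y) for _, y in dataset])
    if set(labels.tolist()) != {0, 1}:
        raise ValueError("training needs both classes (labels 0 and 1)")
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 examples per class")

    rng = np.random.default_rng(cfg.seed)
    seqs = [np.asarray(s.steps, dtype=np.float64) for s, _ in dataset]
    lengths = np.array([len(s) for s in seqs])
    train_idx, val_idx = _stratified_split(labels, cfg.val_fraction, rng)

    train_steps = np.concatenate([seqs[i] for i in train_idx], axis=0)
    model.scaler_mean = train_steps.mean(axis=0).astype(np.float32)
    std = train_steps.std(axis=0)
    model.scaler_std = np.where(std < 1e-8, 1.0, std).astype(np.float32)
    scaled = [model._scale(s) for s in seqs]

    # Adam state
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    t_step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def eval_loss(idx) -> float:
        losses, ns = [], []
        for batch in _batches_by_length(np.asarray(idx), lengths, cfg.batch_size):
            X = np.stack([scaled[i] for i in batch])
            prob, _ = model._forward(X)
            losses.append(_bce(prob, labels[batch]) * len(batch))
            ns.append(len(batch))
        return float(np.sum(losses) / np.sum(ns))

    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    history: list[dict] = []
    stale = 0
    for epoch in range(cfg.epochs):
        perm = train_idx.copy()
        rng.shuffle(perm)
        epoch_loss, n_seen = 0.0, 0
        for batch in _batches_by_length(perm, lengths, cfg.batch_size):
            X = np.stack([scaled[i] for i in batch])
            y = labels[batch].astype(np.float32)
            prob, cache = model._forward(X)
            loss = _bce(prob, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or inspect the features"
                )
            dlogit = ((prob - y) / len(batch)).astype(np.float32)
            grads = model._backward(cache, dlogit)
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            scale = min(1.0, cfg.clip_norm / (gnorm + 1e-12))
            t_step += 1
            bc1 = 1 - beta1**t_step
            bc2 = 1 - beta2**t_step
            for k, g in grads.items():
                g = (g * scale).astype(np.float32)
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                model.params[k] -= (
                    cfg.learning_rate * (m_state[k] / bc1) / (np.sqrt(v_state[k] / bc2) + eps)
                )
            epoch_loss += loss * len(batch)
            n_seen += len(batch)
        val_loss = eval_loss(val_idx) if len(val_idx) else epoch_loss / n_seen
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_seen, "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
        logger.info("epoch %d train %.4f val %.4f", epoch, epoch_loss / n_seen, val_loss)
        if stale >= cfg.patience:
            logger.info("early stop at epoch %d (no val improvement)", epoch)
            break
    model.params = best_params
    return model, history
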