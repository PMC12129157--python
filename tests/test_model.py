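"""Classifier construction, training behaviour and prediction contract."""

import numpy as np
import pytest

from vocog import (
    CognitiveVoiceClassifier,
    FeatureSequence,
    ModelConfig,
    Prediction,
    TrainConfig,
    build_model,
    predict,
    train,
)
from vocog.evaluation import roc_auc

SMALL_CFG = ModelConfig(fc_pre=(32, 16), lstm_hidden=8, fc_head=(16, 8))


def random_sequences(n, t=6, seed=0, separate=False):
    """Random feature sequences; ``separate`` shifts class 1 for separability."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = i % 2
        steps = rng.normal(size=(t, 1028))
        if separate and label:
            steps[:, :50] += 3.0
        out.append((FeatureSequence(steps), label))
    return out


def test_default_parameter_count_pinned():
    """Architecture drift guard: closed-form count of the default config.

    fc_pre 1028->1128->768 (ReLU), two Bi-LSTM layers of 512 units per
    direction, head 1024->1024->512, sigmoid output.
    """
    h = 512
    expected = (
        (1028 * 1128 + 1128) + (1128 * 768 + 768)
        + 2 * ((768 * 4 * h + h * 4 * h + 4 * h))      # layer 1, both directions
        + 2 * ((2 * h * 4 * h + h * 4 * h + 4 * h))    # layer 2, both directions
        + (1024 * 1024 + 1024) + (1024 * 512 + 512)
        + (512 * 1 + 1)
    )
    model = build_model(seed=0)
    assert model.param_count() == expected == 15_145_225


def test_seeded_build_reproducible():
    a = build_model(SMALL_CFG, seed=11)
    b = build_model(SMALL_CFG, seed=11)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])
    c = build_model(SMALL_CFG, seed=12)
    assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


def test_forward_probability_in_unit_interval():
    model = build_model(ModelConfig(), seed=0)
    seq = FeatureSequence(np.random.default_rng(0).normal(size=(14, 1028)))
    p = model.predict_proba(seq)
    assert 0.0 <= p <= 1.0


def test_prediction_threshold_rule():
    assert Prediction(0.4734).decision == "CN"
    assert Prediction(0.5).decision == "CD"  # ties resolve to CD
    assert Prediction(0.8704).decision == "CD"


def test_step_dimension_validated():
    with pytest.raises(ValueError):
        FeatureSequence(np.zeros((3, 500)))


def test_training_rejects_degenerate_datasets():
    model = build_model(SMALL_CFG, seed=0)
    ds = random_sequences(6)
    with pytest.raises(ValueError, match="both classes"):
        train(model, [(s, 1) for s, _ in ds])
    with pytest.raises(ValueError, match="2 examples"):
        train(model, ds[:3])


def test_training_improves_and_history_is_recorded():
    model = build_model(SMALL_CFG, seed=0)
    ds = random_sequences(24, seed=1, separate=True)
    model, history = train(model, ds, TrainConfig(epochs=15, seed=0, learning_rate=3e-3))
    assert len(history) >= 1
    best = np.minimum.accumulate([h["val_loss"] for h in history])
    assert np.all(np.diff(best) <= 0)  # best-so-far never worsens
    assert history[-1]["train_loss"] < history[0]["train_loss"]


def test_training_separates_separable_classes():
    model = build_model(SMALL_CFG, seed=0)
    ds = random_sequences(32, seed=2, separate=True)
    model, _ = train(model, ds, TrainConfig(epochs=25, seed=0, learning_rate=3e-3))
    held = random_sequences(16, seed=99, separate=True)
    pairs = [(model.predict_proba(s), y) for s, y in held]
    auc, _ = roc_auc(pairs)
    assert auc >= 0.9


def test_label_flip_inverts_ranking():
    ds = random_sequences(32, seed=3, separate=True)
    flipped = [(s, 1 - y) for s, y in ds]
    cfg = TrainConfig(epochs=25, seed=0, learning_rate=3e-3)
    m1, _ = train(build_model(SMALL_CFG, seed=0), ds, cfg)
    m2, _ = train(build_model(SMALL_CFG, seed=0), flipped, cfg)
    held = random_sequences(16, seed=98, separate=True)
    auc1, _ = roc_auc([(m1.predict_proba(s), y) for s, y in held])
    auc2, _ = roc_auc([(m2.predict_proba(s), y) for s, y in held])
    assert auc1 >= 0.9
    assert auc2 <= 1.0 - auc1 + 0.2  # flipped labels invert the ranking


def test_forward_is_order_sensitive():
    model = build_model(SMALL_CFG, seed=0)
    ds = random_sequences(12, seed=4, separate=True)
    model, _ = train(model, ds, TrainConfig(epochs=5, seed=0, learning_rate=3e-3))
    rng = np.random.default_rng(5)
    steps = rng.normal(size=(8, 1028))
    p_fwd = model.predict_proba(FeatureSequence(steps))
    p_rev = model.predict_proba(FeatureSequence(steps[::-1]))
    assert p_fwd != p_rev


def test_checkpoint_roundtrip(tmp_path):
    model = build_model(SMALL_CFG, seed=0)
    ds = random_sequences(12, seed=6, separate=True)
    tcfg = TrainConfig(epochs=3, seed=0, learning_rate=3e-3)
    model, _ = train(model, ds, tcfg)
    p = tmp_path / "m.ckpt.npz"
    model.save(p, train_cfg=tcfg)
    back = CognitiveVoiceClassifier.load(p)
    seq = ds[0][0]
    assert back.predict_proba(seq) == model.predict_proba(seq)
    assert back.cfg == model.cfg


def test_variable_length_batching():
    rng = np.random.default_rng(7)
    ds = [(FeatureSequence(rng.normal(size=(t, 1028))), i % 2)
          for i, t in enumerate([4, 4, 6, 6, 8, 8, 4, 6])]
    model = build_model(SMALL_CFG, seed=0)
    model, history = train(model, ds, TrainConfig(epochs=2, seed=0))
    assert len(history) == 2
    out = predict(model, ds[0][0])
    assert out.decision in ("CD", "CN")
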