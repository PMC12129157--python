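"""The synthetic prosody generator: determinism and phenotype recovery."""

import numpy as np
import pytest

from vocog import (
    CD_PARAMS,
    CN_PARAMS,
    CorpusSpec,
    PhenotypeParams,
    SynthesisError,
    label_from_mmse,
    load_manifest,
    narrow_gap_spec,
    synth_corpus,
    synth_utterance,
)
from vocog.synthetic import generate_corpus


def silent_fraction(clip, frame=320, rms_thresh=0.01):
    """Energy-threshold oracle: fraction of 20-ms frames below threshold."""
    x = clip.samples[: len(clip) // frame * frame].reshape(-1, frame)
    return float((np.sqrt((x**2).mean(axis=1)) < rms_thresh).mean())


def test_same_seed_bit_identical():
    a = synth_utterance(CN_PARAMS, 10.0, seed=4)
    b = synth_utterance(CN_PARAMS, 10.0, seed=4)
    np.testing.assert_array_equal(a.samples, b.samples)
    c = synth_utterance(CN_PARAMS, 10.0, seed=5)
    assert not np.array_equal(a.samples, c.samples)


def test_exact_duration_and_range():
    clip = synth_utterance(CD_PARAMS, 37.0, seed=1)
    assert len(clip) == 37 * 16000
    assert np.max(np.abs(clip.samples)) <= 1.0


@pytest.mark.parametrize("params", [CN_PARAMS, CD_PARAMS])
def test_pause_ratio_realized(params):
    clip = synth_utterance(params, 60.0, seed=2)
    assert abs(silent_fraction(clip) - params.pause_ratio) <= 0.05


def test_pitch_variability_recovered():
    """Estimated F0 spread tracks the configured per-syllable spread."""
    from vocog import extract_f0_voicing, make_segments, rms_normalize

    for params in (CN_PARAMS, CD_PARAMS):
        clip = rms_normalize(synth_utterance(params, 60.0, seed=11))
        _, windows = make_segments(clip)
        voiced = []
        for w in windows:
            f0, _ = extract_f0_voicing(w)
            voiced.append(f0.values[f0.values > 0])
        sd = float(np.std(np.concatenate(voiced)))
        assert abs(sd - params.f0_sd) <= 0.3 * params.f0_sd


def test_phenotype_separation_in_pause_fraction():
    cn = np.mean([silent_fraction(synth_utterance(CN_PARAMS, 30.0, seed=s)) for s in range(3)])
    cd = np.mean([silent_fraction(synth_utterance(CD_PARAMS, 30.0, seed=s)) for s in range(3)])
    assert cd - cn >= 0.15


def test_infeasible_parameters_rejected():
    with pytest.raises(SynthesisError):
        synth_utterance(PhenotypeParams(pause_ratio=0.95), 10.0, seed=0)
    with pytest.raises(SynthesisError):
        # huge pause ratio with tiny pauses leaves no room for syllables
        synth_utterance(PhenotypeParams(pause_ratio=0.89, mean_pause_s=0.5, syllable_rate=2.0), 10.0, seed=0)
    with pytest.raises(SynthesisError):
        synth_utterance(CN_PARAMS, 3.0, seed=0)
    with pytest.raises(SynthesisError):
        synth_utterance(PhenotypeParams(f0_sd=-1.0), 10.0, seed=0)


def test_corpus_bookkeeping(tmp_path):
    spec = CorpusSpec(n_per_class=3, duration_s=6.0, seed=7)
    manifest = synth_corpus(spec, tmp_path / "corp")
    records = load_manifest(manifest)
    assert len(records) == 6
    assert sum(r.label for r in records) == 3
    for r in records:
        assert (tmp_path / "corp" / r.wav_path).exists()
        assert r.label == label_from_mmse(r.mmse)  # construction matches the rule
    assert (tmp_path / "corp" / "params.json").exists()


def test_corpus_refuses_nonempty_dir(tmp_path):
    out = tmp_path / "corp"
    out.mkdir()
    (out / "existing.txt").write_text("x")
    spec = CorpusSpec(n_per_class=1, duration_s=6.0, seed=1)
    with pytest.raises(FileExistsError, match="force"):
        synth_corpus(spec, out)
    synth_corpus(spec, out, force=True)  # explicit overwrite succeeds


def test_corpus_deterministic_in_memory():
    spec = CorpusSpec(n_per_class=2, duration_s=6.0, seed=9)
    a = generate_corpus(spec)
    b = generate_corpus(spec)
    for (clip_a, row_a), (clip_b, row_b) in zip(a, b):
        np.testing.assert_array_equal(clip_a.samples, clip_b.samples)
        assert row_a == row_b


def test_dose_response_of_class_gap():
    """Shrinking the CN/CD phenotype gap drives held-out AUC toward chance.

    Scaled down (30-s clips, small model) so three trainings stay cheap;
    tolerances are wide — this is a direction check, not a calibration.
    """
    from vocog.model import ModelConfig, TrainConfig
    from vocog.pipeline import run_synthetic_experiment

    small = ModelConfig(fc_pre=(64, 32), lstm_hidden=16, fc_head=(32, 16))
    tcfg = TrainConfig(epochs=20, seed=7, learning_rate=1e-3)
    aucs = {}
    for gap in (1.0, 0.4, 0.0):
        spec = narrow_gap_spec(gap, n_per_class=20, duration_s=30.0, seed=7)
        res = run_synthetic_experiment(
            n_train=10, n_test=10, seed=7, duration_s=30.0,
            spec=spec, model_cfg=small, train_cfg=tcfg,
        )
        aucs[gap] = res["auc"]
    assert aucs[1.0] >= 0.85
    assert aucs[0.0] <= 0.75
    assert aucs[1.0] > aucs[0.0]


def test_narrow_gap_interpolates():
    closed = narrow_gap_spec(0.0)
    assert closed.cd_params == closed.cn_params
    full = narrow_gap_spec(1.0)
    assert full.cd_params.pause_ratio == pytest.approx(CD_PARAMS.pause_ratio)
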