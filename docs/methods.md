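# Methods

`vocog` implements a screening pipeline that estimates, from a short
(~60 s) conversational voice clip, the probability that the speaker is
cognitively declined (CD) as defined by an MMSE score of 23 or lower.
This note records the model, the parameter choices, the numerical
decisions, and what the synthetic test bed does and does not show.

## Pipeline

1. **Standardization** (`audio_io`). Input WAV audio of any PCM rate and
   channel count is mixed to mono (channel average), resampled to
   16 kHz by polyphase filtering (`scipy.signal.resample_poly`, default
   Kaiser window — deterministic across runs), and snapped to the
   16-bit amplitude grid, making a second pass the identity. Level is
   normalized to a target RMS of −20 dBFS (configurable; the method and
   target of the original study's normalization are not public, so a
   common broadcast-style default was adopted). If the required gain
   would clip, the clip is peak-limited instead, trading level accuracy
   against distortion. An optional spectral-gating denoiser (noise
   profile from the lowest-energy 10% of STFT frames, median-filtered
   across frequency so narrowband signal peaks do not inflate their own
   floor; gated bins attenuated by `strength`) is OFF by default: the
   pipeline contract is quiet, single-speaker audio, and denoising must
   not be a hard dependency. Speaker diarization is out of scope for
   the same reason — multi-speaker recordings must be separated
   upstream.

2. **Windowing and traditional features** (`features`). Clips are cut
   into 5-s windows at 4-s hops (1-s overlap); trailing audio shorter
   than a window is discarded (a 60-s clip yields 14 windows, the last
   ending at 57 s), and clips under 5 s are rejected unless explicitly
   zero-padded. Per window:
   - **F0 and voicing probability**, 100 frames on a 50-ms hop. The
     estimator is YIN-type: the cumulative-mean normalized difference
     function (CMNDF) over a 1024-sample frame, searched across the
     60–400 Hz period range (adult conversational speech); the first
     local CMNDF dip below an aperiodicity threshold of 0.15 gives the
     period (first-dip selection prevents octave-down errors), refined
     by parabolic interpolation. Voicing probability is the dip depth
     `1 − CMNDF(τ*)` gated by a logistic function of log frame RMS
     (midpoint 10⁻³, i.e. −60 dBFS), so low-energy pauses score near 0.
     Frames with probability < 0.5 carry F0 = 0 exactly (linear
     interpolation across unvoiced gaps is available by config).
     The frame geometry (50-ms hop → exactly 100 frames per window) is
     the simplest that reproduces the stated 100-value dimensionality;
     the raw tracks are used directly rather than summary statistics.
   - **MFCC aggregate**, 60 values. 20 coefficients per 25-ms frame
     (10-ms hop, 512-point FFT, 40 triangular mel filters, 20–8000 Hz,
     area-normalized, orthonormal DCT-II of the log mel power).
     Aggregation is `[per-coefficient max | mean | mean of first-order
     delta]`; the delta reduction (mean, chosen for symmetry with the
     mean entry) is configurable.

3. **Window embedding** (`encoder`), 768 values, pluggable. The default
   `MockEncoder` projects gain-invariant pooled log-mel statistics
   (per-band mean and spread, centred so a global gain offset cancels)
   through a fixed seeded Gaussian matrix with a tanh squash; it is
   deterministic and exists for pipeline testability, not
   representation quality. An adapter for a pre-trained self-supervised
   speech encoder (HuBERT-base family; final hidden layer, mean-pooled
   over the window — a single layer rather than an average of several,
   the simplest reading of "last layers") is provided behind the
   optional `hubert` extra; the downstream pipeline is encoder-agnostic
   in shapes and formats.

4. **Classifier** (`model`). Per time step the 1028-value vector
   (embedding 768 | voicing 100 | F0 100 | MFCC 60) passes a fully
   connected stack 1028→1128→768 with ReLU; the sequence then feeds a
   two-layer bidirectional LSTM with 512 hidden units per direction;
   the final forward and backward hidden states are concatenated
   (1024 — the natural reading that matches the 1024-wide head) and
   classified through 1024→1024→512→1 with ReLU between head layers
   and a sigmoid output. Probability ≥ 0.5 decides CD, ties to CD.
   The default architecture has 15,145,225 parameters (pinned in a
   test against accidental drift).

   The network is implemented directly on numpy (float32): dense and
   LSTM forward passes, backpropagation through time, Adam. Training
   defaults — binary cross-entropy, Adam at 10⁻⁴, batch 8, ≤50 epochs,
   stratified 20% validation split, model selection by lowest
   validation loss with patience 10, gradient clipping at global norm
   5, Glorot initialization with forget-gate bias 1 — are conventional
   sequence-classification settings, all exposed in `TrainConfig`.
   Dropout/normalization layers are not used. A per-dimension
   standardizer (mean/sd fitted on the training split, stored in the
   checkpoint) brings the heterogeneous streams (F0 in Hz ~180,
   voicing in [0,1], MFCCs ~±10²) onto a common scale; feature files
   themselves stay raw. Equal-length sequences are stacked into
   batches; mixed-length datasets are grouped by length.

5. **Labels and evaluation** (`labeling`, `evaluation`). Labels are
   always recomputed from MMSE (≤23 → CD); a manifest label column is
   only cross-checked. Metrics: confusion counts, accuracy,
   sensitivity, specificity at the 0.5 cutoff, and AUC by pairwise
   concordance `(concordant + ½·tied)/(n₊·n₋)` via the rank-sum
   identity — exact under ties — with the trapezoid integral of the
   threshold-swept ROC kept as a cross-check (they coincide without
   ties). Single-class inputs yield NaN-flagged rates rather than
   silent zeros. The package also ships the published 20-subject
   discrimination test (diagnosis, MMSE, model probability per
   subject) as `table2_fixture()`; evaluating it reproduces accuracy
   0.950, sensitivity 0.875, specificity 1.000 and AUC 0.990 (95 of 96
   CD–CN pairs concordant) exactly. The "average AUC" quoted for the
   original model is consistent with this single test run. (The quoted
   CN-group mean MMSE of 26.8 does not match the 12 published CN rows,
   which average 26.7 at 1 d.p.; only the CD-group mean, 18.4, is
   reproduced here.)

## Synthetic test bed (`synthetic`)

The generator emulates the prosodic phenotype reported for cognitive
decline — slower speech, more and longer pauses, reduced pitch
variability — as alternating bursts of harmonic syllables and silences:

| parameter | CN default | CD default |
|---|---|---|
| syllable rate (syll/s of speaking time) | 4.0 | 2.5 |
| pause ratio (silent fraction) | 0.20 | 0.45 |
| mean pause (s) | 0.4 | 1.2 |
| F0 mean (Hz) | 180 | 180 |
| F0 sd across syllables (Hz) | 30 | 10 |
| amplitude jitter (relative) | 0.1 | 0.1 |

Directions follow the clinical phenomenology; magnitudes are this
package's choice, picked to be learnable but not trivially separable,
and fully config-exposed (`narrow_gap_spec` interpolates CD toward CN
for dose–response checks). Each syllable is a harmonic source (per-
syllable F0 ~ Normal(μ, σ), clipped to 75–380 Hz) shaped by three
fixed vowel-like resonances (500/1500/2500 Hz) and a raised cosine
contour; pauses are gamma-distributed (shape 4). Burst lengths are
drift-corrected so even a single 60-s clip realizes the target pause
ratio within ~±0.01 — without correction the 60-s sampling noise
(sd ≈ 0.03) would swamp the phenotype contrast checks. A −80 dBFS
noise floor stands in for room tone. Synthetic MMSE scores (CD:
uniform 10–23, CN: 24–30) are metadata glue so the labeling path is
exercised; no claim is made that the acoustics encode a particular
score.

What passing the synthetic end-to-end check does show: the feature
streams carry the pause/rate/pitch-variability contrast, the training
loop learns it, and the evaluation layer measures it (held-out AUC
≥ 0.9 at the default gap; permuted training labels drop held-out AUC
to ≈ 0.5). What it does not show: performance on real conversational
speech — no lexical content, no speaker variability beyond pitch draw,
no channel/recording variation, and the mock embedding is not a speech
representation. The published-test fixture, not the synthetic corpus,
is the package's link to real-data performance.

## Problem sizes

The default synthetic experiment trains on 40 + 40 sixty-second clips
and scores 10 + 10 held-out clips with the mock encoder — large enough
for stable separation, small enough to run on a single CPU in a few
minutes. Feature extraction runs ~0.25 s per 60-s clip; training the
full 15.1 M-parameter model takes ~4-5 s per epoch at batch 8.

## Known limitations

- The published description of the original model fixes the
  architecture widths but not the training hyperparameters; every
  value not fixed by it is a conventional default exposed in config.
- The YIN-style voicing probability is a calibrated heuristic (dip
  depth × energy gate), not the full probabilistic-YIN posterior over
  thresholds; on clean synthetic speech it is near-binary, which the
  tests rely on.
- The mock encoder's embeddings are gain-invariant but carry only
  spectral-envelope statistics; swap in the pretrained adapter for any
  real-data use.
- WAV is the only supported container; diarization, streaming capture
  and MMSE regression are out of scope.
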