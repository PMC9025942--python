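# Methods

## Problem and pipeline

The package classifies fixed windows ("chunks") of single-channel ECG into
three rhythm classes (ARR, CHF, NSR). A chunk — not a beat and not a whole
recording — is the classification unit: 500 samples (~3.9 s at 128 Hz) cut
blindly from the head of the recording, with no QRS detection, beat
alignment, filtering or amplitude normalisation. Denoising is delegated
entirely to the time–frequency representation: broadband noise spreads
across wavelet scales while rhythm and beat morphology concentrate along
ridges of the scalogram.

Stages: resample to 128 Hz → balance classes (30 recordings each) → segment
(10 × 500-sample chunks per recording, `floor(len/500)` available, remainder
discarded) → CWT scalogram → RGB image → CNN→LSTM classifier.

## Continuous wavelet transform

The analytic Morlet wavelet (centre angular frequency ω₀ = 6) is evaluated
in the frequency domain:

    W(s, b) = ifft( x̂(ω) · ψ̂(sω) ),   ψ̂(ω) = exp(−(ω − ω₀)²/2) for ω > 0, else 0,

with L1 scale normalisation so equal-amplitude sinusoids produce equal ridge
magnitudes at every frequency. Because ψ̂(0) = 0 exactly, the response to
constant input is zero to FFT round-off — the defining zero-mean property of
a wavelet. A time-domain implementation built on sampled wavelets was
rejected after it showed ~7e-2 relative DC leakage on 500-sample chunks: at
the lowest analysed frequency the wavelet support exceeds the chunk, and
sampled-kernel boundary handling leaks. The test suite cross-checks ridge
locations against a direct time-domain transcription of the CWT definition
on a 10× denser scale grid.

Parameters (`CWTConfig`):

* `voices_per_octave` = 12 — scales per factor-of-two frequency band;
* `min_cycles` = 2.0 — the slowest analysed oscillation completes two cycles
  within one chunk, giving f_min = 2·fs/chunk_len ≈ 0.51 Hz for the default
  chunk; the scale range is otherwise unconstrained by the source material,
  so this is this package's own convention;
* grid spans [f_min, Nyquist], ascending, exactly log-spaced.

Chunks are reflection-padded by one chunk length on each side before the
transform and cropped back, so cone-of-influence columns are filled rather
than zero-leaking.

**Rendering.** Magnitudes are min–max scaled per image (rendering is
therefore invariant to positive rescaling of the signal), mapped through a
jet-like palette (configurable; tests avoid palette-dependent assertions),
flipped so low frequencies sit at the bottom, and bilinearly resized to
227×227×3 (default) or any requested size. An all-constant magnitude matrix
renders uniformly at the palette's low end rather than dividing by zero.
Per-image min–max (not global, not log) is the simplest defensible scaling;
`render_scalogram` accepts any colormap name if log compression or another
palette is wanted.

## Network

Channels-last NumPy implementation with hand-written backward passes —
there is no deep-learning framework dependency, which keeps the model fully
inspectable and exactly reproducible. Correctness is enforced by
central-difference gradient checks through the full stack and by
independent-transcription oracles for the LSTM step and the convolution
geometry.

* **Conv blocks**: Conv2D (im2col) → ReLU → normalisation → 2×2 stride-2
  max pool. Output geometry follows ⌊(dim + 2p − f)/s⌋ + 1. Block 1 uses
  cross-channel (local response) normalisation with a 5-channel window
  (k = 2, α = 1e-4, β = 0.75); later blocks use batch normalisation
  (ε = 0.001, population variance, running statistics with momentum 0.9 in
  eval mode).
* **Sequence folding**: the CNN trunk runs independently per image; the
  final feature map's rows (top to bottom) form the LSTM's input sequence of
  length H with feature dimension W×C. This reading reconciles a
  per-image sequence architecture with per-chunk classification counts.
* **LSTM**: single layer, peephole gates as printed in the source equations —
  all three gates (forget, input, output) read the *previous* cell state
  C_{t−1} through full H×H peephole matrices. (Common framework LSTMs use
  diagonal peepholes and feed c_t to the output gate; `peephole=False`
  disables the terms entirely for parity testing.) The classifier consumes
  the last hidden state. Default hidden size is 32 — the grid-search
  operating point — rather than the alternative printed value of 4096,
  which remains constructible via `ModelSpec`.
* **Head**: fully connected layers with ReLU, dropout (default rate 0.5,
  inverted, seeded) before the final layer, then a 3-way softmax
  (max-subtraction stabilised).
* **Initialisation** (unspecified in the source material): variance-scaling
  fan-in normal for conv/dense, 1/√fan-in for LSTM matrices, forget-gate
  bias 1; all from a seeded generator, so construction is deterministic.

Two presets: `ModelSpec()` follows the published intent (64/128/256 filter
blocks at 227×227 input) — its printed layer-by-layer tensor shapes are
arithmetically inconsistent, so the implementation trusts the convolution
arithmetic and records the true shape trace at build time;
`ModelSpec.scaled_down()` (8/16 filters, 112×112 input, LSTM 32, ~67k
parameters) is the desk-scale configuration used by the tests and the
acceptance script.

## Loss, optimizer, protocols

The printed cost U = (1/m) Σ [r log s + (1−r) log(1−s)] lacks the
conventional negative sign and has binary form; it is implemented as the
negated (minimisable) sum over the three one-vs-rest class terms of the
softmax output, matching the stated "binary cross entropy". Probabilities
are clipped at 1e-12. A strict categorical cross-entropy (−Σ r log s) is
available via `loss_mode="categorical"`.

The source states three different learning rates in different places (0.01;
0.1; 1e-4 with 0.95/1000 decay). The default follows the most specific
statement: Adam at 1e-4 with stepwise decay lr·0.95^⌊step/1000⌋. The
desk-scale preset (`Hyperparams.scaled_down()`) uses 1e-3 for 10 epochs with
mini-batches of 10 — a standard small-network Adam setting chosen once for
the scaled problem. Adagrad and Adadelta are provided as alternatives. Early
stopping is off (fixed-epoch training); a non-finite loss raises a
divergence error carrying the last good weights (grid search scores such a
point by what those weights still achieve).

Splits: stratified hold-out with per-class test size round(n_c · fraction)
(default 0.30 — the experiment-section figure; the abstract's 75/25 is
reachable via config), and stratified K-fold with exact partitions (per-fold
class counts within one item). `split_unit="chunk"` mirrors the per-image
evaluation pool; **chunk-level splitting leaks recording identity across
train and test**, since chunks of one recording share morphology and noise
realisation — `split_unit="record"` keeps all chunks of a recording in one
fold and is the honest generalisation estimate. Grid search evaluates the
full cartesian product and ranks by mean cross-validated accuracy (percent);
the scoring protocol behind the published mean test scores is unstated, so
those scores are not reproduced.

## Synthetic data generator

The generator stands in for the three clinical databases. Each beat is a sum
of Gaussian bumps (P, Q, R, S, T at fixed offsets/widths); beats are placed
at RR intervals drawn i.i.d. normal (floored at 0.25·mean), plus a slow
sinusoidal baseline wander (0.15–0.35 Hz, 0.05 mV) and white noise
(0.03 mV). Class phenotypes (defaults, chosen once as physiologically
plausible caricatures):

| class | heart rate | RR CV | ectopy prob. | T-wave scale |
|-------|-----------:|------:|-------------:|-------------:|
| NSR   | 75 bpm     | 0.03  | 0            | 1.0          |
| ARR   | 85 bpm     | 0.28  | 0.25         | 1.0          |
| CHF   | 115 bpm    | 0.04  | 0            | 0.25         |

Ectopic beats are wide-QRS, P-less, premature (interval ×0.7) templates.
Per-record seeds derive from (global seed, class, index) via
`numpy.random.SeedSequence`, so datasets are byte-reproducible and enlarging
a dataset only appends records.

What it does **not** emulate: real MIT-BIH/BIDMC waveform statistics,
electrode artefacts, power-line interference, non-stationary rhythm changes,
atrial-fibrillation-specific P-wave morphology, or inter-patient
variability. Classes differ by construction in rhythm regularity and
morphology, so a high synthetic classification accuracy demonstrates that
the pipeline wiring, transform and optimiser work — it says nothing about
clinical performance on real recordings.

## Problem sizes and numerical choices

The default experiment configuration uses 30 recordings per class
(900 chunks), 112×112 scalogram images, the scaled-down model and 10 epochs;
this trains in a few minutes on one CPU and reaches held-out chunk accuracy
in the high-90s percent across seeds. Images are stored uint8 and scaled by
1/255 at batch time; weights are float32 at initialisation and promoted to
float64 through NumPy arithmetic during updates. Resampling uses polyphase
filtering with the rate ratio as a limited-denominator fraction. Ties in max
pooling route the gradient to the first maximal element. Zero-denominator
metrics are NaN with a warning, never silently 0 or 1, and macro averages
are unweighted (classes are balanced by design).

Stage caching in the experiment runner keys the scalogram image set on a
hash of the generating configuration (not on file contents — at this scale
recomputation is cheaper than content hashing); `--force` bypasses it.
Timing and hardware details go to `provenance.log` only, never into
`metrics.json`, so reruns with one config and seed are bit-identical.

## Known limitations

* Chunk-level evaluation (the default, mirroring the published protocol)
  overstates generalisation; use `split_unit="record"`.
* The paper-fidelity `ModelSpec()` at 227×227 with 4096-unit layers is
  constructible but not trained in the tests; only the scaled-down
  configuration has an empirical accuracy claim here, and that claim is
  about synthetic data.
* Which 10 of the 131 available chunks, and which subset of the larger
  classes, the original study used is unstated; this package takes the first
  ones (deterministic) and exposes `offset_strategy="random"` /
  `strategy="random"` as alternatives.
* WFDB ingestion covers text headers with format-16 signals only.
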