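# Methods

`ppg2ecg` reconstructs missing stretches of a single-lead ECG from the
photoplethysmogram (PPG) recorded simultaneously on the same subject. The
physiological premise is that every cardiac contraction produces both an
electrical signature (the ECG's QRS complex) and, after the pulse arrival
time (PAT), a mechanical one (the PPG's systolic upstroke), so the PPG
carries enough beat-timing and morphology information to interpolate an ECG
segment that was lost — for example when an electrode detaches during
long-term monitoring.

## Pipeline

For each paired record (ECG + PPG, both at `fs` = 125 Hz):

1. **Filtering.** Zero-phase Chebyshev type-II bandpass: 0.5–10 Hz for PPG,
   0.5–20 Hz for ECG. The design places the stopband corners one octave
   outside the stated passband with 40 dB attenuation, because a type-II
   filter is specified by its stopband; the prototype order is 4. Forward–
   backward application (`sosfiltfilt`) keeps peak positions unshifted,
   which the next step depends on.
2. **Peak detection.** R peaks by the Pan–Tompkins chain (5–15 Hz bandpass,
   derivative, squaring, 150 ms moving-window integration, adaptive dual
   thresholds with search-back, 200 ms refractory, apex refinement in a
   ±75 ms window). PPG systolic peaks by two event-related moving averages
   (clipped–squared signal, 111 ms peak MA vs 667 ms beat MA plus an offset
   of 2 % of the mean squared amplitude, minimum block width 111 ms, block
   argmax, 300 ms minimum separation).
3. **Alignment I (lag removal).** The third systolic peak is matched to the
   nearest R peak at or before it (PPG physiologically trails ECG), the PPG
   is advanced by that lag and both channels are truncated to the common
   overlap. On synthetic data the recovered lag equals `pat_s * fs` within
   one sample and the residual median systolic−R offset is ≤ 2 samples for
   PAT anywhere in 0–0.4 s.
4. **Normalisation and segmentation.** Both channels are min–max scaled to
   [0, 1] per record; the first 294 s are kept and cut into 98
   non-overlapping 3 s segments of 375 samples. Scaling the ECG target
   (the reference protocol prescribes scaling only for the PPG) keeps it inside
   the Tanh output range of the network; this is the one deliberate
   extension and it is config-visible.
5. **Split.** Chronological 60/20/20: segments 0–57 train, 58–77
   validation, 78–97 test.
6. **Gap injection.** One contiguous span of 1, 2, 3 or 4 s of ECG is
   zeroed at a seeded uniform position inside the training portion, with an
   explicit boolean mask carried alongside (spans may cross segment
   boundaries). The test-portion reference stays intact so the metrics are
   well defined. One gap per record per experiment.

## Models

**WNet** is two cascaded 1-D U-shaped encoder–decoders. Each U has four
down blocks (conv kernel 4, stride 2, batch norm, ReLU; lengths
384→192→96→48→24, channels 32→64→128→256), dropout 0.5 at the bottleneck,
and four up blocks (transposed conv kernel 4, stride 2, batch norm, ReLU)
with skip concatenation from the same-level encoder output. Input segments
(375 samples) are constant-padded to 384 on entry — 375 is odd and cannot
survive repeated halving — and cropped back on exit; the second U's output
passes a 1×1 convolution activated by Tanh. **WNet-BiLSTM** additionally
runs one bidirectional LSTM over the 24 bottleneck steps of the second U
(hidden size 128 per direction, concatenated back to 256 channels),
modelling the beat-to-beat envelope between the contraction and expansion
paths. Where the reference architecture leaves the wiring open (depth,
widths, which bottleneck hosts the BiLSTM, whether dropout appears in both
U-blocks) the choices above are ours, standard U-Net practice, and all
isolated in `ModelSpec` — including an optional upsample+conv substitute
for the transposed convolutions (off by default).

The layers are implemented directly in NumPy with explicit
backpropagation; convolutions are lowered to one large GEMM per layer.
Every layer and both U-block compositions are checked against central
finite differences in float64 (the gradient checks jitter the parameters
first, because at initialisation zero biases put ReLU pre-activations
exactly on the non-differentiable kink, and a conv bias feeding a
train-mode batch norm correctly has zero gradient).

## Training

Plain per-sample mean squared error between reference and reconstructed
segment; zero-filled gap samples are included in the mean by default
(the literal objective), and a `masked_loss` flag restricts the mean to
present samples. Adam (β = 0.9/0.999, ε = 1e-8) with base learning rate
1e-3 decayed by 0.1 every 100 epochs — the decay rule's "steps" are read
as epochs, since per-batch stepping would freeze the optimiser a fraction
of the way into the first epoch at these dataset sizes. Protocol-scale
defaults are 500 epochs at batch 128; the model returned is the
minimum-validation-loss checkpoint (the reference protocol names a
validation split but no selection rule; this is the conventional one). One group model is trained jointly across all
records. All randomness — gap placement, weight init, dropout, batch
shuffling — flows from the run seed through named child seeds, so a run
is fully determined by its configuration and inputs.

## Stitching, Alignment II and metrics

Reconstructed test segments are concatenated in order (no overlap or
smoothing) and realigned to the reference by maximising normalised
cross-correlation over integer lags in ±1 s (the lag bound is our
choice; 1 s comfortably covers any residual group delay). Lag 0 is
always a candidate, so realignment can never reduce the correlation.
After shifting, the series keeps its length via edge-value padding so the
sample count is identical with and without alignment.

Metrics, computed per record on the whole test portion (58.8 s), before
and after Alignment II:

* Pearson's r;
* RMSE;
* PRD = 100 · √(Σ(E−Er)² / ΣE²);
* Fréchet distance. Distance formulations that index both curves with a
  single shared subscript are not well defined; we implement the standard
  *discrete* Fréchet distance on the amplitude sequences (the
  Eiter–Mannila dynamic programme): the minimum, over monotone couplings
  of the two sequences, of the maximum pointwise distance.
  The DP is verified against an exhaustive coupling enumeration
  on short sequences and is numba-compiled for the 7 350-sample test
  portions.

Summaries report mean ± sample standard deviation across records per
experiment (labels I–IV ↔ gaps 1–4 s).

## Synthetic data

No clinical waveforms ship with the package; the generator provides paired
records with known ground truth. ECG beats are sums of five Gaussian bumps
— P(0.15, −0.20 s, 0.04 s), Q(−0.15, −0.04 s, 0.012 s), R(1.0, 0, 0.014 s),
S(−0.2, +0.035 s, 0.014 s), T(0.3, +0.28 s, 0.06 s) as (amplitude, offset
from R, width) — on a beat train whose inter-beat intervals are
Normal(60/hr, hrv_sd) truncated at 0.3 s, first beat fixed at 0.5 s so edge
beats are whole. The PPG is a systolic Gaussian per beat delayed by
`pat_s`, plus an optional dicrotic lobe (amplitude 0.25 at +0.30 s), plus
white noise; an optional 0.2 Hz sinusoid emulates baseline wander and
exercises the 0.5 Hz high-pass edge. Defaults (70 bpm, hrv 0.03 s, PAT
0.24 s, noise SD 0.02 of the unit R amplitude) sit in the middle of resting
adult physiology.

What this emulates: beat timing with variability, P–T morphology, the
ECG→PPG lag, broadband noise, contiguous signal loss. What it does not:
arrhythmia, beat-to-beat morphology change, motion artefact, pathological
PPG shapes, or any nonlinear ECG↔PPG relationship beyond shared beat
timing — so passing tests demonstrate that the pipeline's machinery
(detection, alignment, learning, stitching, metrics) is correct, not that
clinical-grade reconstruction accuracy transfers to ICU recordings.

## Problem sizes

At clinical scale this protocol would train on the order of 150
five-minute ICU records for 500 epochs; the package's own experiments run
at desk scale. The parameter-recovery
check trains a WNet for 150 epochs at batch 32 on 10 synthetic records
(294 s each, 2 s gaps, noise SD 0.02) and requires held-out per-record
mean r ≥ 0.7 after Alignment II — a correctness bar, not a clinical
benchmark; the
measured value is ≈ 0.98, and realignment never lowers the mean
correlation. `scripts/acceptance.py` uses 8 records and 100 epochs for
the same flow. At these sizes the synthetic task is easier than the
clinical one (the generator's PPG→ECG map is nearly deterministic), which
is precisely what makes it a correctness oracle rather than a performance
benchmark.

## Known limitations

* The NumPy training loop is single-threaded BLAS; protocol-scale runs
  (146 records × 500 epochs) are possible but slow.
* WFDB reading supports single-segment format-16 records only.
* Fréchet distance on long series is exact but O(n·m); windowed evaluation
  (`--window-seconds`-style) is left to the caller slicing the series.
* The Fréchet distance is often nearly invariant under small realignment
  shifts (warping absorbs them); we compute and report it both before and
  after Alignment II rather than assuming equality.
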