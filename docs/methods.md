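# Methods

This note documents the models and procedures implemented in `beatfusion`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic-data experiments do and do not show.

## Signal model and synthetic data

A record is a single ECG lead in millivolts. The generator renders each
beat as a sum of five Gaussian bumps (P, Q, R, S, T) whose amplitudes,
widths and offsets are class-specific; five default templates evoke the
AAMI beat groups (normal; supraventricular with small P and low R;
ventricular with wide, large QRS and no P; fusion; unclassifiable/paced
with low R and broad T). R-R intervals are the nominal heart-rate interval
scaled per beat by `1 + U(−j, +j)` with jitter fraction `j` (default 0.1),
which exercises the heart-rate-adaptive cropping path. Three noise terms
are added on top of the clean template sum:

| term | default | emulates |
|---|---|---|
| baseline sinusoid | 0.10 mV at 0.3 Hz | respiratory baseline wander |
| powerline sinusoid | 0.02 mV at 50 Hz | mains interference |
| broadband Gaussian | σ = 0.05 mV | EMG / electronics noise |

Defaults put the smallest inter-class R-amplitude gap (0.2 mV) at 4σ of
the broadband noise, so classes are separable by construction — a
nearest-centroid classifier on raw beats exceeds 90 % accuracy, which is
the precondition for using this data to validate the training pipeline.
The generator is phenomenological: it does not model conduction dynamics,
morphology drift within a class, inter-patient variability, electrode
artefacts, or multi-lead geometry. Passing end-to-end tests on it
demonstrates that the pipeline's machinery (segmentation arithmetic,
featurization, optimisation, evaluation) is correct and that the model
can learn class-discriminative time-frequency structure; it does not
predict accuracy on clinical recordings.

## Denoising

Wavelet thresholding uses an 8-level `db4` decomposition. The noise scale
σ is estimated once from the finest detail level as `median(|d|)/0.6745`
— estimating per level would treat genuine low-frequency signal content
as noise and over-threshold. Each detail level is soft-thresholded at
`σ·t*`, where `t*` minimises Stein's unbiased risk estimate over that
level's coefficients (a universal-threshold rule is available as an
alternative). Signals too short for 8 levels fall back to the maximum
admissible depth with a warning. Baseline wander is removed by
subtracting a running median with window `round(0.30 × fs)` samples (108
at 360 Hz), reflect-padded at the edges; a constant input therefore maps
exactly to zero.

## R-peak detection

Records without beat annotations (the CSV/rhythm layout) go through a
Pan-Tompkins-style detector: 5–15 Hz band-pass (2nd-order Butterworth,
zero-phase), rectified derivative, 150 ms moving-window integration,
candidate peaks at a minimum 200 ms spacing. The adaptive threshold is an
Otsu split of the log integration-peak heights into QRS and noise
clusters — a plain fraction-of-median threshold proved brittle when QRS
energies span an order of magnitude across beat classes. Candidates
arriving within 360 ms of the last accepted beat at less than half its
height are rejected as T waves. Each accepted candidate snaps to the
absolute-amplitude maximum within ±50 ms. On the seeded 60 bpm benchmark
configuration the detector's recall and precision both exceed 0.95.
Annotated records always use their annotations; the detector never
overrides them.

## Segmentation

Fixed mode (360 Hz layout) takes 143 samples left and 144 right of the R
sample (288 total, the R sample counted in the left half) and 431/432 for
the three-cycle window (864 total); the single-cycle window is exactly
the middle third of the three-cycle window. Adaptive mode (500 Hz layout)
computes the per-record cycle length `Ns = 60/Hr × Sr` from the median
R-R interval — the median is robust to ectopic beats — and crops
`round(Ns/2)` and `round(3Ns/2)` samples per side, with round-half-up as
the tie rule; crops are then resized to 400 and 1200 samples, so the
pre-resize length parity is immaterial downstream. Beats whose
three-cycle window runs outside the record are skipped at both scales
(the pairing is never broken) and counted, never raised.

Resizing is cubic-convolution (Keys kernel, a = −0.5) expressed as a
precomputed interpolation matrix with edge-aligned coordinate mapping and
linear extrapolation past the ends, so constants and straight lines are
reproduced exactly and the operation is exactly linear — which also gives
the network's fusion resize an exact gradient (the transposed matrix).

## Spectrograms

Window length and hop are `round(0.2 × fs)` and `round(0.01 × fs)`
samples: 72/4 at 360 Hz and 100/5 at the nominal 500 Hz used for resized
adaptive segments. Frames are taken without zero-padding, each tapered by
the Kaiser window `w(n) = I₀(πα√(1−(2n/(N−1)−1)²))/I₀(πα)` and passed
through an N-point DFT with N equal to the window length; all N magnitude
bins are kept as rows, although rows r and N−r are redundant for real
input, because the classifier consumes the full image. The frame count is
`⌊(L−N)/hop⌋ + 1`: 55/199 frames for 288/864-sample segments at 360 Hz
and 61/221 for 400/1200-sample segments at 500 Hz. The window shape
parameter α defaults to 3 (moderate side-lobe suppression); no result
here is sensitive to it. Magnitude is linear by default with a log1p
option.

## Mixup

New samples are `εx_a + (1−ε)x_b` with ε ~ Beta(1,1) (uniform), applied
to three-cycle signals; the paired single-cycle signal is re-extracted as
the central window of the mix, which by linearity equals the ε-mix of the
parents' single cycles. Parents are two distinct samples of the same
class (cross-class mixing with genuinely soft labels exists behind a
flag but is off by default): intra-class mixing keeps labels hard, which
is what makes exact per-class post-augmentation counts
`n + round(r·n)` (round-half-up) well defined. Default generation ratios
oversample S by 1.0, V by 0.5 and F by 2.0. Augmentation runs strictly
after the train/test split and augmented samples carry a provenance flag,
so they can never leak into evaluation.

## Classifier

Branch A consumes the single-cycle spectrogram with 3×3 kernels, branch B
the three-cycle spectrogram with 5×5 kernels. Each branch stacks four
stride-1 same-padded conv+ReLU layers with 4, 8, 16, 32 filters — no
pooling, so spatial shape is preserved end to end — with SE gates after
the third and fourth convolutions. An SE gate squeezes each channel by
global average pooling, passes the channel vector through FC C→C/2 with
ReLU and FC C/2→C with sigmoid, and rescales the channels by the result;
since the gate is strictly below 1 it never amplifies. The reduction
ratio 2 gives FC widths 16→8→16 and 32→16→32. Branch B's 32-channel map
is bicubically resized per channel onto branch A's spatial grid and the
two maps are summed element-wise; the fused map passes through a
trainable per-channel normalization (batch statistics with learned affine
and running averages for inference), is flattened, and classified by a
64-unit ReLU layer and a softmax output (5 classes for the beat scheme, 4
for the rhythm scheme). Spectrograms are standardized per image (zero
mean, unit variance) before entering the network.

Training minimises cross-entropy against target distributions (one-hot or
Mixup-soft) with Adam (default lr 0.001) and seeded shuffling; with a
fixed seed the loss curve and all artifacts reproduce bit-for-bit on a
fixed software stack. The whole network — convolutions as sums of
shifted BLAS matrix products, explicit backward passes, Adam — runs on
numpy in float32; gradient correctness is verified against central
differences in the test suite. Defaults of 30 epochs and batch 256 suit
datasets of ~10⁵ beats; the synthetic experiments below use batch 16 and
6–12 epochs because at a few hundred training samples a 256-batch would
give a single parameter update per epoch.

Ablation variants are config switches: single-branch models drop the
other branch and the fusion, and `use_se=False` removes the SE gates.

## Evaluation

Metrics are one-vs-rest per class from the confusion matrix, as
percentages: Acc = (TP+TN)/total, Sen = TP/(TP+FN), PPV = TP/(TP+FP),
F1 = harmonic mean of Sen and PPV; macro scores are unweighted arithmetic
means over classes, and overall accuracy is the trace ratio. Per-class
accuracy is one-vs-rest (TN counts every correct non-class outcome) —
the only reading under which accuracy is a per-class quantity.
Zero-denominator metrics evaluate to 0 and set a named flag rather than
raising or propagating NaN. Internal values keep full precision;
rounding to two decimals happens only at presentation.

## Experiment sizing and what the synthetic results show

The end-to-end check trains the full model on 6 synthetic records × 50
beats (≈ 290 beat pairs, 85/15 split, Mixup on) for 6 epochs and exceeds
90 % held-out accuracy in a few minutes on one CPU core. The SE ablation
trains the full and the no-SE multi-input variants to convergence
(12 epochs) on a compact adaptive layout (80/240-sample segments,
20-row spectrograms) for ten seeds: the SE model's Macro-F1 is greater
or equal in 8 of 10 runs. On this separable synthetic data both variants
typically sit at or near ceiling, so the comparison mainly verifies that
channel attention does not degrade a converged model; demonstrating the
accuracy *gains* the mechanism brings on real recordings requires the
real databases, whose headline numbers are outside desk scale.

## Known limitations

- The WFDB codec covers the text header, format-16 signals and the
  beat-annotation subset (with SKIP/NUM/SUB/CHN/AUX handling on read);
  other signal formats are rejected explicitly.
- The numpy network is single-threaded BLAS-bound; it is sized for
  hundreds-to-thousands of beats, not the full 97k-beat corpus.
- Per-record rhythm labels (CSV layout) label every detected beat with
  the record's rhythm; beat-level pathology within a rhythm is not
  modelled.
- The R-peak detector is validated on synthetic morphology only and is
  never used when annotations exist.
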