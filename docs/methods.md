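# Methods

## Problem and scope

`emghand` is a desk-scale re-implementation of a single-channel myoelectric
hand-prosthesis control pipeline: surface-EMG trials are conditioned by an
(emulated) analog front end, digitized, reduced to a 20-element hybrid
feature vector, and classified into one of five gestures — closed hand, grip,
index, middle, ring — by a 20-15-5 multilayer perceptron trained with
Levenberg-Marquardt. Because no subject recordings are distributed with this
package, the input stage is a seeded synthetic-EMG generator; everything
downstream is agnostic to where the trials came from, and user-supplied
single-channel CSV/WAV signals can be substituted.

Physical hardware — electrodes, microcontroller firmware, servomotors, the
printed prosthesis — is out of scope; the servo interface is emulated as a
stream of per-finger angle commands.

## Synthetic EMG model

A trial is band-limited Gaussian noise shaped by a contraction envelope:

    x(t) = A * env(t) * n_B(t),   n_B = 4th-order Butterworth band-pass of
                                        white Gaussian noise over band B

- `env(t)` is a union of raised-cosine (Hann) bursts over a 2% baseline tone,
  with per-trial onset jitter (±30 ms).
- Per class, the burst count (1–3), widths, peak amplitude `A`
  (0.9–3.0 mV, ±15% per-trial jitter) and band `B` (inside 55–145 Hz)
  differ, which is what makes the five classes statistically separable.
  Real per-gesture differences at a single electrode site are not this
  clean; the class-conditional structure is a stand-in, so classification
  accuracies measured here characterize the pipeline, not human subjects.
- The trace is rescaled so its peak equals `A`, keeping every trial under
  the 10 mV physiological ceiling and — after the ×651 chain gain — inside
  the 0–5 V ADC range, mirroring how the hardware gains were tuned.
- Bands sit strictly inside the 50–150 Hz dominant-energy region so the
  trial PSD peaks there (verified on 100 seeded trials).
- Optional contamination: additive mains sinusoid (50/60 Hz, inside the
  pass-band, hence deliberately *not* removed by the front end) and
  baseline wander below 20 Hz (removed by the high-pass). Both default to
  zero amplitude.
- Determinism: every trial's RNG is keyed by `(seed, class_id, trial_index)`,
  so sessions are reproducible bit-for-bit and the 90-movement operational
  test can draw provably fresh trials by using a large trial-index offset.

The internal simulation rate is 10 kHz, leaving headroom above the 500 Hz
band edge before the 1 kHz ADC stage. Default trial duration is 0.8 s
(800 digitized samples), enough to let the windowing stage make a
non-trivial choice of the 500-sample region of interest.

What the generator does **not** emulate: motor-unit action potentials and
recruitment, electrode-skin impedance drift, multi-channel cross-talk,
fatigue, inter-session electrode placement variability. Passing tests
therefore demonstrate correctness of the processing chain and trainability
of the classifier under the stated spectral/amplitude assumptions — not
expected accuracy on real subjects.

## Front-end emulation

Stages, in order: instrumentation pre-amplifier (gain
`(R4/R3)(2 R2/R1 + 1)`, tuned to 31), 3rd-order Butterworth low-pass
(design 500 Hz, realized 471 Hz), 3rd-order Butterworth high-pass (design
20 Hz, realized 22.7 Hz), non-inverting final gain (`1 + R_fb/R_in`,
range 1–30, tuned to 21; out-of-range requests are clamped with a logged
warning), DC offset (default 2.5 V = ADC mid-scale; a 1.5 V preset is
provided), and a 10-bit 0–5 V ADC at 1 kHz (round-half-up quantization,
saturating with a clip counter, stride decimation from 10 kHz — the
low-pass has already bounded content below the 500 Hz Nyquist limit of the
1 kHz stage).

Total default gain is 31 × 21 = 651. Filters are bilinear-transform
realizations of the analog Butterworth prototype (scipy design, prewarped
at the cutoff) applied once, causally, as a real-time analog chain would
be — not zero-phase. Consequence of the bilinear map: the −3 dB point is
exact at `fc`, but near the Nyquist rate the digital response is compressed
relative to the analytic `|H(f)| = (1 + (f/fc)^6)^(-1/2)`. At the 10 kHz
operating rate the emulation tracks the analytic magnitude closely through
the EMG band; the two-decade 0.2 dB fidelity check is evaluated at 200 kHz,
where warping is below 0.05 dB everywhere in `[fc/10, 10 fc]`. The realized
chain is parameterized by cutoff frequency only; printed RC component
values are not modeled.

## Acquisition and windowing

Session accounting is exact: at 1 kHz, a 60 s session is 60,000 samples and
(at 2 bytes/sample) 120,000 serialized bytes. The protocol collects 50
trials per gesture (250 total). Each digitized trial is mapped back to
volts (offset removed), mean-centered, and reduced to the 500-sample window
maximizing total energy — computed by cumulative sums, equivalent to an
exhaustive scan, with ties broken at the earliest start (within a 1e-12
relative tolerance so float round-off cannot flip a tie). A flat trial
yields the centered window flagged `no_burst`. Splits are stratified by
class with largest-remainder apportionment and a seeded shuffle, so 250
balanced vectors split exactly 150/100 (60/40) or 150/50/50 (60/20/20).

## Feature conventions

Choices the definitions leave open, fixed here:

- **ZC/SSC deadband** defaults to 0 (literal strict inequalities); real EMG
  practice uses a small positive deadband against sensor noise, so it is a
  parameter.
- **AR estimation** uses Burg's method (statsmodels), convention
  `x(k) = Σ a_i x(k−i) + e(k)`; Yule-Walker could be swapped in. The test
  suite cross-checks against an independent textbook Burg lattice recursion
  and against parameter recovery on simulated AR(1)/AR(2) processes, with
  error decreasing over N ∈ {500, 5,000, 50,000}.
- **Energy normalization** is Parseval-consistent: `E = (1/N) Σ|X_k|²
  = Σ x_n²`, so time- and frequency-domain computations agree to 1e-9
  relative and the three rectangular STFT windows partition the total
  energy exactly. Mean power is `E/len(window)`; a non-divisible segment
  appends the remainder to the last window.
- **Wavelet**: Daubechies db5 (10 taps), 5 levels, symmetric boundary
  extension; the feature is the *sample* variance (N−1) of the
  approximation coefficients at each level (a detail-coefficient variant is
  available as an option). The minimum segment length for 5 levels is 288
  samples; 500-sample windows are safe.
- **Degenerate input**: a constant segment has zero-variance AR input; the
  fit returns zero coefficients with a flagged zero residual variance, and
  the zero trial maps to the all-zero feature vector.
- **Standardization**: features span orders of magnitude (counts vs
  energies), which saturates sigmoid inputs; per-feature z-scores are fit
  on the training split only and stored with the model. Toggleable.

The feature count is exactly 20: 4 time-domain scalars, 3 AR coefficients,
2 FFT scalars, 2 per STFT window (×3), and 5 wavelet variances.
Periodogram/spectrogram arrays are intermediate representations, not
features.

## Classifier and trainers

The 20-15-5 network uses logistic sigmoid hidden *and* output units with
an MSE objective on one-hot targets (consistent with the perceptron error
rule `e = z − y`); argmax decodes the gesture, ties to the lowest class id.
Arbitrary layer sizes and identity activations are supported, which gives
the linear special case used to check Levenberg-Marquardt against the
normal-equations least-squares solution, and small nets for
finite-difference Jacobian verification.

LM solves `(JᵀJ + μI)Δ = −Jᵀr` with `J = ∂r/∂θ` computed by per-output
backpropagation; μ starts at 1e-3, ×10 on a rejected step (training MSE
rose), ×0.1 on acceptance, aborting at μ > 1e10. A singular system simply
escalates μ. Accepted steps therefore never increase training MSE. The
comparison trainers are BFGS (inverse-Hessian update, Armijo backtracking
line search, falling back to steepest descent when the curvature condition
fails), Polak-Ribière conjugate gradient (non-negative β, restart every
`n_params` iterations or on a non-descent direction), one-step secant
(memoryless quasi-Newton from the last parameter/gradient differences), and
variable-learning-rate gradient descent with momentum (rate ×1.05 on
improvement; step rejected and rate ×0.7 when MSE grows by more than 4%).
All five share batch epochs, a goal-MSE stop, and early stopping after 6
consecutive validation failures; the returned model is the snapshot at the
best validation epoch, whose validation MSE equals the minimum of the
curve. Initialization is seeded (`N(0, 1/fan_in)` weights, zero biases) and
the five-way comparison starts every algorithm from the same
initialization.

## Evaluation

Confusion matrices are exact counts (rows true, columns predicted);
accuracy is `100·trace/total`. The operational test draws `n = 90` random
gestures uniformly, pushes each fresh trial through conditioning,
windowing, feature extraction and the trained network, and reports the
percentage of correctly replicated movements ("assertiveness") with its
error complement. Gesture-to-servo decoding is a fixed total map to five
per-finger angles in [0°, 180°] (closed hand = all flexed, grip = power
grasp preshape, finger gestures flex one finger); the angles are a software
calibration, stored in one table, that a hardware user would re-tune.

## Problem sizes and determinism

The default study conditions are the full protocol — 5 gestures × 50 trials
× 500 points, a 20 × 250 feature matrix, 60/40 or 60/20/20 splits, and the
90-movement operational test. The complete pipeline (generation through LM
training and the operational test) runs in a few seconds on one CPU, so
tests and the acceptance script use these sizes unreduced. All randomness
(generation, splits, initialization, protocol draws) flows from explicit
integer seeds.

## Known limitations

- Single channel; no inter-subject or inter-session variability model.
- The synthetic classes are separable by construction; reported accuracies
  (validation ≈ 93–98%, operational test ≈ 87–97% across seeds) bound the
  pipeline's behavior under the stated assumptions, not clinical
  performance.
- The bilinear filter realization deviates from the analog magnitude near
  the operating Nyquist rate (see above).
- The LM Jacobian is dense; the implementation targets sub-thousand
  parameter networks, not large models.
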