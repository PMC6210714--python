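# Methods

## The estimation problem

Surface EMG amplitude grows with the force a muscle produces, so a
high-density grid over the biceps brachii carries enough information to
reconstruct the elbow-flexion force trace.  The pipeline treats this as a
sequence-to-sequence regression: a Q-point window of the conditioned sEMG
input is mapped to the Q-point force window recorded simultaneously.  All
forces are expressed as fractions of the subject's maximum voluntary
contraction (MVC) and normalized per contraction cycle, so the regression
target lies in [0, 1].

## Synthetic acquisition model

Real recordings of this kind are not publicly deposited, so the package
ships a generator whose outputs have the statistical structure the
analysis needs.  Channel k of the grid records

    emg_k(t) = w_k · g · f(t)^α · c_k(t) + σ · ξ_k(t) + a · sin(2π·50·t + φ)

where `f(t)` is the trapezoidal force trace (2 s linear ramp to the target
level, 4 s hold, 1 s linear relaxation inside the rest second, 1 kHz, with
optional smooth tracking jitter ≤ 2% MVC), `c_k` is a unit-variance
Gaussian carrier band-limited to 20–450 Hz, `ξ_k` is white noise, and the
last term is common 50 Hz line interference.  The spatial weights `w_k`
form a 2-D Gaussian bump over the 16 × 8 grid (peak 1).  Two to four
channels per recording are corrupted (flat-lined or rail-saturated), as
real grids produce.

Parameter defaults, chosen once as a realistic operating point:

| parameter | default | meaning |
|---|---|---|
| gain g | 3 (2–4 across subjects) | peak-channel amplitude per unit force, arbitrary units |
| α | 1 (0.9–1.3) | force-to-amplitude exponent; 1 = linear envelope–force link |
| activation spread | 2.5 grid units (2–3) | Gaussian width of the activation map, ≈ 2 cm at 8 mm pitch |
| baseline noise σ | 0.1 | white-noise floor relative to a unit-variance carrier |
| line amplitude a | 0.02 (0.01–0.03) | residual 50 Hz after grounding |
| bad channels | 2–4 per recording | flat or saturated electrodes |

The spread/noise pair matters for identifiability: channel selection can
only be validated against ground truth if channels *differ* after
per-cycle normalization.  With a very broad bump and little noise every
normalized envelope is the same force-shaped curve (the envelope matrix is
essentially rank 1) and any rank-2 factorization splits it arbitrarily.
At the default operating point the peripheral channels are visibly
noise-dominated, the factorization separates a force-tracking pattern from
a noise-floor pattern, and the selection typically recovers 85–95% of the
ground-truth top-32 channels (≥ 75% averaged over seeds).  The rule is
least robust at the lowest force level: per-cycle normalization makes the
noise-floor fraction largest there, the two patterns' intensities come
within a few percent of each other, and the intensity comparison can
occasionally pick the floor pattern — whose weighting factors rank the
channels in exactly the wrong order.  Recoveries for such a recording drop
sharply while the other levels stay above 90%.

What the generator does **not** emulate: motor-unit action-potential
trains, conduction velocity, inter-channel correlation from shared motor
units (carriers are independent per channel), electrode lift-off dynamics,
and muscle fatigue.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its statistical assumptions are
sufficient — not that the specific accuracies transfer to human data.

## Conditioning chain

Order: bad-channel replacement → band-pass → PCA spatial filter →
envelope → per-cycle normalization.

* **Bad channels** are replaced by a seeded-uniformly chosen good
  4-neighbor on the grid (an error if none exists).  Detection is out of
  scope; channels arrive flagged.
* **Band-pass**: 20–499 Hz window-design FIR, Hann, 50th order (51 taps).
  The upper edge is 499 Hz because 500 Hz equals Nyquist at 1 kHz and is
  not realizable.  The taps are de-meaned to place an exact null at DC: at
  51 taps the raw window design leaves ≈ 18% DC gain, which would let
  electrode offset through; the correction perturbs the pass band by
  < 0.5%.  Filtering is zero-phase (forward–backward) by default so
  envelopes stay time-aligned with force; a causal, group-delay-compensated
  variant is a config switch.
* **PCA spatial filter**: channels are variables, samples observations;
  modes are covariance eigenvectors sorted by descending variance.  The
  first two and last two are dropped and the rest reconstructed with
  channel means restored.  Computed per recording.  Note the operation is
  not idempotent under repeated application with the same drop counts —
  the second pass re-ranks the surviving modes and removes two more; what
  is stable is the retained subspace (re-filtering while dropping only the
  dead modes is the identity).
* **Envelope**: full-wave rectification then 5 Hz low-pass (same FIR
  family); negative ripple is clipped to zero.
* **Normalization**: each envelope channel and the force trace are divided
  by their own maximum within each contraction cycle; all-zero cycles are
  left untouched.

## NMF channel selection

The normalized envelope matrix M (m = 128 channels × n samples) is
factorized as M ≈ W C with s = 2 by Lee–Seung multiplicative updates on
the Frobenius loss — seeded uniform (0, 1] initialization, best of 5
restarts, tolerance 1e−6 on the per-iteration error decrease, at most 500
iterations.  The per-iteration relative error trajectory is logged (and is
non-increasing, a property of the updates).

Scale ambiguity: W columns are normalized to unit **sum**, compensating in
C.  The intensity Σ_t C_i(t) of a pattern then measures the total
activation it explains across all channels, so the major-pattern choice is
invariant to the factorization's arbitrary scaling and a pattern loaded by
the bulk of the grid dominates one that only absorbs a few noisy
electrodes.  (Normalizing columns to unit *maximum* instead makes the
noise-floor pattern — whose C row carries the floor level — win the
intensity comparison on this generator and selects exactly the wrong
channels.)  Ranking within a pattern is unaffected by column scaling; ties
break toward the lower channel index.

Because envelopes are band-limited to 5 Hz, the NMF is fitted on every
20th sample by default (`time_stride=20`, i.e. a 50 Hz grid) — a 20-fold
cost reduction with no measurable effect on the spatial factors.  The
averaged signal is always assembled at full resolution.

## Data sets and circumstances

Allocation is at contraction-cycle granularity with a seeded shuffle:

* **subject-dependent** — one subject, 80/10/10 train/dev/test;
* **multi-subject** — per subject 80% into a pooled training set and 10%
  into a pooled dev set; the remaining 10% kept as per-subject test pools;
* **subject-independent** — leave-one-subject-out; the others split 90/10.

Cycles assigned to a pool are concatenated per subject (levels mix, as in
multi-force training; subjects never mix) and random truncation draws
R = 50,000/100/100 windows by default — scaled in tests and the acceptance
study to 2,000/100/100.  Start indices are uniform with replacement on the
1-based range [1, (P−1)Q]; a window starting at k covers samples
k … k+Q−1, so every admissible window fits inside the record.  With
multiple pools, a pool is chosen with probability proportional to its
admissible-start count.

Scaled studies use Q = 289 = 17² instead of the full-scale 6889 = 83²;
each 7000-sample cycle is linearly resampled to Q points (the same kind of
length adjustment that fitting a ~7 s cycle into a square-number window
implies).  Envelopes are 5 Hz band-limited, so resampling to 289 points
(≈ 41 Hz) preserves their shape.

## Architectures and training

All models end in a linear fully-connected head of width Q; predictions
may over/undershoot [0, 1] and the loss sees them raw.

* **CNN**: row-major reshape of the Q-point sample to √Q × √Q, then
  conv(3×3, same padding) → batch-norm → ReLU → 2×2 max-pool blocks
  (defaults 16/32/64 filters), flatten, dropout 0.5, linear head.
* **LSTM**: the sample as Q/frame_size timesteps of frame_size features
  through an LSTM (default 128 hidden units, frame_size 1); the full
  output sequence is flattened into the head.  frame_size must divide Q;
  tests and the acceptance study use frame_size 17 at Q 289, which is
  dramatically cheaper than per-sample timesteps and loses nothing
  measurable at this scale.
* **C-LSTM**: 1-D strided convolution (default 32 filters, kernel 16,
  stride 8, valid padding) → batch-norm → ReLU → LSTM → flatten → head.

Training minimizes the batch RMSE% as a single ratio over the concatenated
batch (matching the metric's definition; a per-sample mean is a config
alternative) with Adam (lr 1e−3, batch 32), both defaults standard for
these architectures.  The development loss — mean per-sample RMSE% in
evaluation mode — is computed every epoch; training stops after six
consecutive strict increases (the laxer above-the-minimum reading is a
config switch) or at max_epochs (default 200 as a safety bound), and the
best-epoch parameters are restored.  Everything is seeded; on a
single-threaded CPU runs are bit-reproducible.

## Statistics

* **RMSE%** is undefined for an identically zero measured-force window
  (an error, per its definition).
* **Bland–Altman**: differences d = F̂ − F, limits mean ± 1.96 · sd
  (sample sd, ddof = 1), plus the fraction of points within the limits.
* **Kruskal–Wallis** (scipy's tie-corrected H with the χ² approximation)
  is applied pairwise to per-sample RMSE% distributions of two model
  families at a time.  The fully-tied case returns H = 0, p = 1 rather
  than an undefined 0/0 tie correction, so stub-model comparisons behave.

## Numerical and degenerate-input choices

* Envelope ripple below zero is clipped; identically zero cycles pass
  through normalization unchanged.
* NMF rejects negative or all-zero input; s must satisfy 0 < s < min(m, n).
* PCA with fewer samples than channels proceeds with a rank-deficiency
  warning.
* Ties: major-pattern and channel-ranking ties break toward the lower
  index (stable sort).
* Training aborts with a diagnostic on a non-finite loss instead of
  silently continuing.

## Known limitations

* The carriers are spatially independent, so the PCA stage's leading modes
  align with the loudest channels rather than a shared neural drive; with
  correlated real data the same stage removes common-mode content.  The
  stated recovery and accuracy properties hold either way, but PCA's
  benefit is understated on synthetic data.
* Accuracies reported by the scaled studies (1–5% RMSE) reflect the
  generator's clean force–envelope link and are far better than what human
  recordings yield; only the orderings (sequence models over CNN,
  varied-pattern over fixed-pattern, multi-force over single-force) are
  meaningful claims.
* No GPU path and no automatic hyperparameter search; the shipped defaults
  were tuned by hand on development sets at desk scale.
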