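# Methods

This note documents the model, the numerical choices, what the synthetic
generator does and does not emulate, and the design decisions taken where the
method left genuine latitude. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pipeline

1. **Filtering.** Zero-phase low-pass Butterworth (default 5 Hz, order 2),
   applied forward–backward per channel (`scipy.signal.sosfiltfilt`). The
   bidirectional pass squares the magnitude response and cancels phase, so
   plateau levels and event timing are preserved. Cutoff must be below
   Nyquist; recordings shorter than the filter's padding length are rejected.

2. **Anatomical frame (`frame_mode: auto`, default).** Camera axes are
   arbitrary, so each recording is re-expressed in a frame estimated from the
   data: the lateral axis is the time-averaged right→left direction across the
   shoulder and hip pairs; the superior axis is the mean trunk direction
   (spine base → neck) over the frames of greatest leg extension (standing),
   orthogonalized against the lateral axis; the anterior axis is their cross
   product with the sign fixed by the lean direction at peak trunk
   inclination. Every step is equivariant under rotation, translation and
   positive scaling of the input, which makes the *whole* pipeline
   similarity-invariant to float precision. This is the package's resolution
   of a real tension: per-channel standardization (below) is not invariant
   under a rotation of the raw coordinates, so invariance has to be secured
   before channels are formed, not after. `frame_mode: fixed` trusts the
   stored axes (y superior, z anterior) instead.

3. **Segmentation.** The superior coordinate of the neck is the segmentation
   signal (largest, cleanest displacement in sit-to-stand). Seated and
   standing levels are its 10th/90th percentiles; an upward crossing of their
   midpoint marks a rise. Onset is the last *prominent* local minimum before
   the crossing — the forward-lean dip; a prominence floor of 10 % of the
   seated–standing span rejects noise wiggles that a literal "last local
   minimum" rule would latch onto. Offset is the first sample from which the
   signal stays within a plateau band (default ±5 % of the span) around the
   standing level for a dwell time (default 0.2 s). Recordings whose span is
   below 0.10 m are rejected as static. The first repetition is always
   discarded (habituation); repetitions 2–5 are analyzed in the canonical
   5-repetition protocol.

4. **Temporal normalization.** Time is min–max rescaled to 0–100 % and
   positions are linearly interpolated onto a uniform grid of `grid_size`
   points (default 101, i.e. integer percent; the method states the range but
   not the resolution). Endpoints are exactly 0 and 100.

5. **Standardization.** Each of the J = 33 scalar channels (3 axes × 11
   landmarks; PCA operates on scalar channels) is centered over time and
   scaled to unit variance (denominator T−1). Channels whose standard
   deviation falls below 1e−8 × the median channel SD are dropped rather than
   noise-amplified. At reference-fit time the retained set is the
   intersection across the control cohort; that set is stored in the
   reference and is authoritative for every scored subject thereafter, so a
   subject's channel set — and hence score — can never depend on which other
   subjects are in a batch.

## Scoring model

Per repetition, the covariance (= correlation, after standardization) of the
standardized matrix is eigendecomposed; all K = J components are kept, so
P Wᵀ reconstructs X exactly and Σλ = J. Deterministic orientation: each
loading column's largest-magnitude entry is made positive, then the basis is
canonicalized to det(W) = +1 by flipping the smallest-eigenvalue column if
necessary. The determinant canonicalization matters because the Procrustes
rotation is constrained to be proper (no reflections): without it, two
subjects whose bases happened to differ by an improper transform could never
be brought into register.

The T×K score configurations of all control repetitions enter an iterative
GPA (full Procrustes fit of each configuration to the consensus — optimal
translation, proper rotation by SVD/polar solution, scale — then consensus ←
mean of aligned shapes, renormalized to unit Frobenius size to prevent
shrinkage; convergence when the consensus moves < 1e−9, error after 100
iterations). The converged consensus is translated so its t = 0 row (the
seated rest pose) sits at the origin; no further rotation is applied, which
fixes the anchor deterministically since GPA itself is deterministic given
input order.

Every subject — control or patient — is then fitted to the frozen consensus
in a single pass, per repetition. The subject's own eigenvalues weight the
aligned component trajectories into the K-Profile. Weights are constant in
time (a single per-subject PCA has one eigenvalue per component; a printed
time index on λ has no referent). Raw eigenvalues are used rather than
explained-variance ratios; after standardization the two differ exactly by
the constant J, which the α calibration absorbs.

Per-repetition profiles are averaged pointwise and repetition durations
averaged into Tᵢ (score-level aggregation preserves per-repetition
diagnostics; the method is silent on where to aggregate). DF is the
trapezoidal integral of |profile − control mean profile| over [0, 100], and

    KScore = 100 − (1/α) · (Tᵢ / T̄_ctrl) · DFᵢ.

α is fitted once on the control cohort: α = mean[(Tᵢ/T̄)·DFᵢ] / (100 −
target), making the control mean score equal the target (default 94.0,
configurable) exactly. α is never re-fitted per patient.

**Alignment target.** Subjects are aligned to the *control-only* consensus,
never to an all-cohort consensus. An all-cohort consensus would make every
score depend on the batch composition, destroying the method's defining
sample-size-independence property; reference-anchored alignment is the only
reading consistent with that property and is what the package implements and
tests (bit-identical scores alone vs. in batches of 10/50/200).

## Comparators

- **Isolated torso metrics**: peak trunk flexion (spine base → neck axis vs
  vertical, sagittal projection, degrees); peak SVA (anterior shoulder-over-
  hip offset / height); peak superior/anterior velocity of the torso COM
  proxy (unweighted mean of the 5 trunk landmarks), normalized by
  √(g·leg length); peak accelerations normalized by g. Derivatives are
  central differences on the original clock (one-sided at ends). Leg length
  defaults to the landmark-derived first-frame estimate (hip→knee + knee→
  ankle, averaged over sides); height falls back to a skeleton-based estimate
  when missing.
- **Across-patient PCA**: each repetition's pose sequence is per-frame
  full-Procrustes aligned to the control-average seated pose, flattened
  time-major into one (T·J) row, and a single PCA is fitted across all rows
  after column standardization, retaining the smallest m with cumulative
  explained variance ≥ 0.90 (the retained count is data-dependent — "5 PCs"
  is a dataset outcome, not a method constant). Per-frame (not
  whole-trajectory) alignment was chosen because the step exists to remove
  positioning/orientation/scale nuisance, which varies frame by frame.

## Synthetic generator

The generator emulates what the pipeline needs to be exercised end-to-end:
an 11-landmark skeleton with segment lengths fixed as stature fractions
(thigh 0.245 h, shank 0.246 h, trunk 0.30 h, shoulder width 0.259 h, pelvis
width 0.191 h), a 0.432 m (17 in) chair, repetitions structured as rest →
forward lean → minimum-jerk rise → standing plateau → eccentric descent, with
per-repetition timing/amplitude jitter, additive white Gaussian position
noise (default SD 3 mm, Kinect-like), and a small mediolateral weight shift
locked to each rise plus a faint idiosyncratic sway so all 33 channels carry
genuine signal. The trunk flexion peak falls 25 % into the rise, where both
the flexion decline and the hip rise move at mid-range rates — this puts the
neck-height minimum (the detected onset) at a sharply curved point, keeping
event detection stable under noise.

Impairment is a severity dial acting through three axes: extra peak flexion,
a slowdown factor (which also injects a mid-rise hesitation into the hip
trajectory, so slow movers deviate in curve *shape*, not just clock time —
pure time dilation would be removed by temporal normalization), and
left–right asymmetry (foot-placement offset plus amplified lateral shift,
always in the subject's own shift direction so the lateral variance never
passes through zero). Slowness carries an always-on share of the severity
budget; the flexion and asymmetry shares are mixed randomly per patient in
cohort generation, mimicking the clinical heterogeneity that defeats any
single isolated metric. Cohorts generated with the same seed at different
severities contain identical subjects (the severity dial is the only
difference), which is what makes matched severity-arm comparisons clean.

Ground truth stored per trial: event times of the noise-free signal under
the same event definition the detector uses (so segmentation tests measure
robustness to noise and filtering, not definition agreement), commanded phase
boundaries, commanded peak flexion, clean peak COM velocities, and exact
segment lengths.

What the generator does **not** emulate — and hence what a green test does
not establish: soft-tissue and tracking artifacts with temporal structure
(dropouts, swaps, autocorrelated noise), true multi-joint redundancy beyond
the planar-dominant model, armrest use or failed rises, and any calibrated
correspondence between the severity dial and a clinical scale. Cohort-level
numbers (medians, effect sizes) are properties of this stated synthetic
world, not reproductions of any clinical cohort.

## Numerical choices and degenerate inputs

- GPA: tolerance 1e−9 on the consensus displacement, max 100 iterations,
  consensus unit-normalized each round, reflections forbidden throughout.
- Procrustes scale is guarded to stay positive (degenerate anti-correlated
  configurations fall back to unit scale); zero-size configurations are
  rejected.
- PCA sign ties (a column whose largest-magnitude entries tie) resolve to the
  first occurrence; eigenvalues are clipped at zero against roundoff.
- Trapezoidal integration for DF — exact for the piecewise-linear profiles
  the grid representation defines.
- Missing/NaN samples are rejected, not interpolated (no gap-filling is part
  of the method); a pluggable pre-filter hook slot is the intended place for
  an external biomechanical-constraints cleanup, default identity.
- Calibration requires at least one control with DF > 0 and a target strictly
  below 100; otherwise α is undefined and the fit errors out.
- Per-subject failures during batch scoring (static trial, too few
  repetitions) flag the row and continue; only an insufficient control cohort
  aborts a run.

## Known limitations

- The anatomical-frame estimate leans on the standing trunk being near
  vertical; subjects with fixed sagittal deformity would tilt the frame and
  bias the flexion metric (not the K-Score, which is frame-invariant by
  construction of the estimate).
- K-Profiles are only defined up to the control consensus's orientation;
  profiles from references fitted on different control cohorts are not
  directly comparable, and neither are K-Scores calibrated to different
  targets.
- The score compresses all deviation into one number; it flags *that* a
  subject deviates, not *where* — the per-repetition aligned score
  trajectories are retained for that purpose.
- Linear PCA assumes near-linear channel relationships; adequate for the
  sit-to-stand transfer, not guaranteed for complex dynamic tasks.
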