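# Methods

This note documents the models, statistical rules, numerical choices and
known limits of the package. It is written for users who need to know what
the computations assume, not how the code is organized.

## Data model and whitening

A trial is a point in data space: the concatenation of every marker's
x/y/z trajectories over 101 normalized stance time points (marker-major,
then axis, then time; all user-facing indices 1-based, so marker 3 /
vertical / time 39 is variable 847 of 3939 in the 13-marker layout).
Preprocessing of raw capture data runs filter → stance crop → time
normalization → centering/scaling, in that fixed order so filter edge
transients stay outside the stance window:

- zero-phase low-pass Butterworth, cutoff 12 Hz, net order 4 (realized as a
  forward–backward pass of order 2, standard biomechanics practice; a
  single-pass causal variant is available);
- stance = the first contiguous episode where vertical ground-reaction force
  is ≥ 15 N (first crossing = initial contact, last frame of the episode =
  toe-off). A force trace sampled faster than the cameras is decimated to
  the kinematic clock by nearest-frame lookup;
- resampling to 101 equidistant points by cubic spline (endpoint-exact and
  deterministic; the classical polyphase FIR resampler differs only in the
  sub-sample interior and both stay within interpolation tolerance for
  band-limited trajectories);
- horizontal coordinates shifted by the pelvis-marker centroid (per frame by
  default; a per-trial-mean mode exists because the convention differs
  between laboratories), vertical shifted so the trial's lowest point is the
  floor, everything divided by subject height (output dimensionless).

Whitening is per subject and per variable, over that subject's trials *and
conditions pooled* — never per condition, which would erase the effect being
sought. The SD uses the sample (n−1) denominator (configurable). Zero-SD
variables raise by default; an opt-in mode zeroes and flags them to preserve
the column layout. The statistics are retained, so de-whitening is exact to
round-off and reconstruction returns metric trajectories.

## Classifiability testing

All claims of "classifies" are leave-one-subject-out and two-level:

- trial level: a held-out subject with n trials is classifiable if the
  correct count reaches the binomial threshold;
- subject level: a direction classifies significantly if the number of
  classifiable subjects reaches the binomial threshold for the subject count.

Both tests are one-sided (better than chance), p = ½, α = 0.05. `exact`
mode takes the smallest k with P(X ≥ k) ≤ α — 26 of 40 trials, 9 of 11
subjects. `paper` mode reproduces the historical printed counts (25 of 40,
8 of 11), which correspond uniformly to the smallest k with P(X ≥ k+1) ≤ α;
the discrepancy is left to the user by providing both modes, with the active
mode stamped into every report. `paper` is the default for continuity with
the published thresholds; `exact` is recommended for new analyses. No
multiple-testing correction is applied across basis vectors (the historical
procedure applies none); reports carry that caveat.

One-dimensional assignment uses the midpoint rule: threshold halfway between
the two training-condition mean projections, oriented by the larger training
mean. It is deterministic, symmetric, and invariant to affine increasing
transforms of the projections; degenerate ties (equal training means) fall
back to chance with a warning.

## The SVM decomposition

Discriminants come from a soft-margin linear SVM (box constraint C = 1 by
default). The data are already whitened, so no further rescaling is applied
inside the SVM stage — a second scaling would distort the discriminant
direction. The per-step basis vector is the mean of the 11 sign-aligned fold
directions, renormalized to unit length (a basis vector must be unit norm;
fold biases are averaged for reporting only and play no role in the basis).
Accepted directions are Gram–Schmidt-purged against the accepted set
(tolerance 1e−10) purely as a drift guard, then deflated out of the data by
orthogonal projection in the original coordinates (mathematically equivalent
to refitting in a re-parameterized complement, cheaper numerically).
Termination: the first step whose classification rate loses subject-level
significance; the rejected discriminant is logged but never added. Rank
exhaustion and an iteration cap (default 100) are recorded as distinct
termination reasons. The dimensionality of the SVM space is known to be
sensitive to C and to solver details, so C and the threshold mode are part
of every result.

Variance attribution divides the summed squared projections of all rows on a
unit vector by the total sum of squares; over the joint (SVM + complement)
basis the fractions sum to 1 (Parseval), which the test suite asserts to
1e−6.

## ICA refinement

All SVM-space directions separate the same two groups, so their projections
are correlated — the SVM space is redundant. Extended infomax ICA (the
classical EEG-community algorithm; `mne.preprocessing.infomax`) runs on the
trials × m matrix of SVM-space coordinates; a FastICA alternative is
configurable. Source directions are mapped back to data space and
unit-normalized; they span the SVM space but are generally oblique. Because
the base is oblique, the coordinate of a trial along ICA vector j is its
*source value* (the dual-basis functional via the unmixing row), not a raw
dot product — raw projections onto oblique vectors would leak the
discriminant source into every component. Vectors are ordered by
classification rate (ties by effect size), so "first" is the discriminant;
if none is significant that absence is reported as a valid outcome. ICA
solutions are not guaranteed unique; the seed and algorithm are always
recorded, and multi-seed stability is the user's check, not something the
package adjudicates.

## Synthetic data

The generator emulates the study shape: 11 subjects × 2 conditions × 20
trials × 13 markers × 3 axes × 101 time points. Per trial, in
height-normalized units:

    x = b · (1 + a_s) · (1 + ε) + effect + η

with b a smooth per-marker/axis base waveform (sums of 1–3 cycle sinusoids,
amplitude scale 0.25), a_s ~ N(0, 0.1²) a per-subject amplitude effect
(multiplicative, so whitening does not trivially remove it), ε ~ N(0, 0.03²)
per-trial amplitude jitter, and η i.i.d. N(0, 0.01²) measurement noise
(≈ 2 cm on a 1.8 m subject — optical noise plus soft-tissue and marker
placement variability; a Laplace option provides heavier tails for ICA
stress tests). Base waveforms come from a fixed internal design generator:
the movement is part of the experimental design, so the user seed changes
only subject effects, jitter and noise, and the planted truth directions are
identical across seeds.

Two effect shapes exist. A **shift** effect displaces the conditions by
± A/2 along a unit Gaussian bump (default: marker 3, vertical, centered at
time 39, width 8). Effect strength is expressed as `effect_snr`: the
between-condition separation along the planted direction *in whitened
space*, in units of the unit within-subject SD (default 10, i.e. the
projections of the two conditions are 10 SDs apart). The raw amplitude
achieving this is solved in closed form from the expected within-subject
variance (jitter + noise + the effect's own contribution); the separation
saturates at 2·√(support size) because the effect inflates its own
whitening SDs, and unreachable targets raise rather than silently
under-deliver. A **timing** effect gives both conditions the bump but
offsets its center by ± δ/2 between conditions with per-trial timing noise;
the condition difference is then nonlinear in time, which is what produces a
multi-dimensional (redundant) classifying subspace as seen in real gait
data — a pure mean-shift effect always yields a 1-D classifying space. The
truth direction of a timing effect is the quadrature-smoothed mean
difference. An optional per-subject timing jitter shifts bump centers
between subjects.

What the generator does **not** emulate: musculoskeletal dynamics, ground
contact physics, marker occlusion/relabeling, autocorrelated soft-tissue
artifacts, or condition effects on movement variability. Passing tests
therefore demonstrate the estimator's statistical behavior under the stated
model, not biomechanical validity on real recordings.

## Problem sizes and observed behavior

Cross-validated Monte-Carlo checks run at a reduced scale chosen as the
package's test conditions: 11 subjects (kept, so subject-level thresholds
match the study design) × 8 trials per condition × 4 markers × 31 time
points (176 × 372). At whitened SNR 10 the planted direction is recovered
with |cos| ≥ 0.95 across seeds; with no effect the exact-mode iteration
accepts zero discriminants; exactly one ICA vector classifies on
single-effect data. At the full 440 × 3939 scale the same SNR yields
|cos| ≈ 0.90: direction-estimation noise grows with the variables-to-trials
ratio, a property of the problem rather than of the implementation, and
visible in any run's `truth.svm_space_cosines` report field.

## Numerical choices

- Numerical rank: singular values > 1e−10 × the largest.
- PCA fold matching is ordinal (fold vector #k against full-data vector #k)
  with sign alignment by dot product; instability (|cos| < 0.7) is warned
  about per fold, which is common and expected for high-order,
  near-degenerate components.
- SVC stopping tolerance defaults to the solver's 1e−3; hard-margin
  geometry checks tighten it to 1e−12.
- Orthonormality asserted at 1e−8 (pairwise dots) / 1e−10 (norms);
  whiten/de-whiten round trip at 1e−10; full-basis reconstruction at 1e−6.
- Degenerate inputs (single-class labels, zero matrices, empty subspaces,
  zero-SD variables) raise typed exceptions rather than returning NaNs; an
  empty SVM basis is a valid result, not an error.

## Known limitations

- The mean-of-folds discriminant is a heuristic consensus; no optimality is
  claimed for it over, e.g., refitting on all subjects.
- Classification rates are in-sample with respect to model *selection* (the
  stopping rule reuses the same folds); the rates of accepted vectors are
  therefore mildly optimistic.
- The ICA discriminant's uniqueness is not guaranteed and its effect size is
  typically below the first SVM vector's; both are reported so users can
  choose.
- Soft-margin C trades margin against dimensionality of the recovered SVM
  space; results should quote C.
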