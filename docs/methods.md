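# Methods

This note documents the models, procedures, numerical choices and known
limitations of the package. It describes what the code computes; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes itself.

## Scientific setting

The package analyses multichannel EEG recorded while an observer mentally
judges short videos of robot actions as optimal or suboptimal. Two
complementary questions drive the design: *where and when* do evoked
responses differ between the two judgments (mass-univariate cluster
statistics on current-source-density maps), and *how well* can the judgment
be read out from single trials or single timepoints (multivariate
decoding). Because the reference dataset is distributed on request only,
the package ships a synthetic-study generator that reproduces the trial
design and the three condition-discriminative spatiotemporal signatures,
so that every stage is testable end to end.

## Synthetic-study generator

Each simulated subject watches 10 blocks of 100 videos (65 optimal, 35
suboptimal, shuffled within block), 1.5 s per video, inter-stimulus
interval uniform on 0.75–1.0 s. Generation is at 250 Hz by default (1,000
Hz available); 250 Hz is transparent to the analysis because the
preprocessing bandpass ends at 10 Hz, and it keeps an 8-subject study
tractable on one CPU.

Condition-discriminative components are injected as focal scalp-potential
Gaussians, `amp · exp(−d²/2σ²)` in great-circle distance `d` from the
nearest center direction, times a temporal envelope:

* **C1, left fronto-temporal (F7/FT9, σ = 0.35 rad)** — `ramp_sustain`:
  zero before 0.42 s, linear rise to a maximum at 1.6 s, then a steep
  decline to 10% at 2.0 s. Amplitude +1.1 µV for suboptimal, −1.1 µV for
  optimal: the current-direction switch of the sustained late signature.
  The late maximum makes the group decoding curve peak in the 1.5–1.8 s
  window, and the post-peak decline gives the late analysis interval the
  within-window waveform structure that covariance-based single-trial
  decoding feeds on.
* **C2, right frontal (Fp2, σ = 0.45 rad)** — Gaussian transient peaking
  at 0.50 s (suboptimal delayed by 40 ms), −0.8 µV optimal vs −2.0 µV
  suboptimal.
* **C3, mid-parietal (P1/Pz/P2/POz, σ = 0.45 rad)** — triphasic: small
  negative dip at ~0.42 s, brief positive peak at 0.55 s, dominant
  sustained negativity from 0.70 to 1.76 s; overall scale 0.8 µV optimal
  vs 1.9 µV suboptimal.

Background activity is a sum of 20 spatially coherent `1/f` sources with
random Gaussian scalp topographies (8 µV RMS per channel total) plus 2 µV
white sensor noise — a typical resting-EEG spectral profile. Per-trial
lognormal gain (σ = 0.3) and latency jitter (σ = 30 ms), a per-subject
lognormal gain (σ = 0.2), and a per-subject angular jitter of the
component centers (0.1 rad) create realistic between-fold,
between-subject and topographic variance. The topographic jitter matters
beyond realism: CSD maps of smooth scalp patterns carry wide opposite-sign
halos, and without inter-subject variability those faint deterministic
fringes become group-significant everywhere and fuse distinct clusters.

Component amplitudes and footprints were calibrated once against the full
pipeline — late-interval single-trial AUC inside the 0.60–0.75 band, the
three signature clusters separately significant at the reduced 8-subject
cohort — and then frozen. Two structural facts shaped the calibration and
are worth knowing when modifying it: the sign-flip permutation null is
inflated by flips of the strong components themselves, so every amplitude
increase also raises the family-wise bar for the other clusters; and
cluster separation depends on the CSD halos of neighbouring components,
so spatial footprints (σ) matter as much as amplitudes. The values are
configuration entries, not empirical claims about physiological effect
sizes, which no public source reports in microvolts.

What the generator does **not** emulate: ocular/muscle artifacts, a
realistic volume-conduction forward model (components are injected directly
as potential topographies), block-order or fatigue effects, and
overlapping-epoch autocorrelation beyond what the continuous noise
provides. Passing tests therefore demonstrate correctness of the analysis
machinery and recoverability of signatures of this geometry and SNR — not
performance on artifact-laden recordings.

## Montage and adjacency

Electrode positions are idealized spherical 10-10 coordinates built from
the standard arc-fraction construction (midline nasion–inion arc in 10%
steps; circumferential ring at the 10% level with 18° azimuth steps;
intermediate electrodes by great-circle interpolation at 25/50/75% between
midline and ring; FT9/FT10, TP9/TP10 one step below the ring). The cap
list is the study's 63 printed labels plus the midline AFz that completes
the AF row, giving the stated 64 channels. Channel adjacency is the edge
set of a Delaunay triangulation of the azimuthal-equidistant projection
about the vertex: parameter-free, symmetric and connected by construction,
and invariant under rotations about the vertical axis.

## Preprocessing

Canonical order: per-channel linear detrend → zero-phase 4th-order
Butterworth bandpass 0.2–10 Hz (applied forward–backward with
second-order sections; the effective amplitude response is the single-pass
response squared) → epoching −0.2 to 2.0 s around video onset (epochs
crossing the recording edge are dropped, never padded) → polyphase
downsampling to 250 Hz → per-epoch bad-channel handling → baseline
subtraction of the mean over [−0.2, 0) s → condition-count equalization.

Bad-channel handling is a deliberate surrogate for ICA-based artifact
pipelines: a virtual EOG channel (mean of Fp1/Fp2) is stored in the
rejection log, and a channel is flagged within an epoch when its amplitude
range or variance is a robust (median/MAD) outlier, either across channels
within the epoch or — when at least 16 epochs are available — across
epochs within the channel. The second direction matters when a majority of
channels in one epoch is corrupted, where the within-epoch median is
itself contaminated. Flagged channels are replaced by spherical-spline
interpolation (the same Perrin g-kernel as the CSD stage); epochs with
more than 20% flagged channels are dropped. The rejection log records
every action and states explicitly that this is not ICA.

Equalization keeps, for the majority condition, the order-preserving
subset whose summed |rank-position| discrepancy against the minority
sequence is minimal. This is solved exactly by a monotone-matching dynamic
program with earliest-index preference on ties, so the result is
deterministic and attains the global minimum of the stated criterion.

## Current source density

The scalp potential is fitted per time sample with a spherical spline,
`v(x) = c₀ + Σᵢ cᵢ g(cos θ(x, xᵢ))`,
`g(t) = (1/4π) Σₙ (2n+1)/(n(n+1))⁴ Pₙ(t)` (50 Legendre terms, stiffness
m = 4), with ridge regularization λ = 10⁻⁵ and the sum-to-zero constraint
on the coefficients. The CSD is the negated surface Laplacian of the
fitted spline, obtained analytically from the companion kernel with
m−1 weights; by the spherical-harmonic identity ΔPₙ = −n(n+1)Pₙ this makes
a focal potential maximum a positive CSD source. The constrained system is
factorized once per montage into a single 64×64 transform matrix; applying
it per time sample is algebraically identical to per-sample solves
(verified to 10⁻¹⁰). Output units are µV per squared unit head radius; all
downstream statistics and classifiers are scale-invariant, so the physical
radius is left at 1.

Two caveats. First, the constants (m, λ, series length) are the customary
defaults of the spline-Laplacian literature, not values reported for the
reference analysis; they are exposed in the configuration and recorded in
the run manifest. Second, the discrete zero-net-current property (CSD
summing to ≈0 across channels) holds only when electrodes tile the whole
sphere; for a half-head cap the channel sum is not small, and the test
suite verifies the property on a full-sphere Fibonacci lattice instead.

## Cluster-mass permutation statistics

Subject-wise contrasts (suboptimal − optimal evoked response; this sign
convention is used everywhere, and reports label it) are tested against
zero with a one-sample t per (channel, time) sample. Samples exceeding the
two-tailed Student-t quantile at α = 0.05 (df = n−1) form clusters under
the standard spatiotemporal lattice: temporal adjacency within a channel,
spatial adjacency within a time sample, no diagonal edges, and only
same-sign samples merge. Cluster mass is the summed t. The null
distribution is the maximum |mass| over per-subject sign flips — the
exchangeability transformation of a paired design — with two-tailed
family-wise control via the absolute maximum. p-values are +1-corrected
Monte-Carlo estimates, so they are never exactly zero.

Implementation note: sign flips leave per-sample sums of squares
unchanged, so the t maps of all permutations reduce to one matrix product;
cluster masses per permutation come from connected components on the
pre-built lattice edge list. This makes 10,000 permutations on desk-scale
grids a matter of seconds and enables the exhaustive 2ⁿ enumeration oracle
(n ≤ 14) against which the Monte-Carlo null is validated.

## Temporal decoding

Per subject and timepoint, the 64-channel CSD vector (100 Hz, 220
timepoints) is classified with a least-squares LDA whose pooled
class-centered covariance is shrunk toward a scaled identity with the
analytic Ledoit-Wolf intensity (implemented in-package, verified against
scikit-learn's estimator to 10⁻¹⁰). Cross-validation is repeated
stratified 5-fold with 20 repetitions (100 fold scores per timepoint);
performance is tie-corrected ROC-AUC. Group inference pools the
subject × fold scores per timepoint, bootstraps the mean (5,000 resamples,
percentile 95% CI), and flags a timepoint significant when its lower CI
bound exceeds the upper CI bound of the pooled dummy baseline. The dummy
draws decision scores independently of the test labels under the identical
CV scheme; its null expectation is AUC 0.5. Peak time is the earliest
maximum of the bootstrap mean.

A calibration caveat the null-decoding test documents and exploits: fold
scores from repeated CV are positively correlated within subject (repeats
retest the same trials), so a bootstrap that resamples folds as if
independent narrows the CI as the repeat count grows, and the significance
rule becomes anti-conservative in the many-repeat, few-subject regime.
Pooling across independent subjects and keeping the repeat count modest
restores calibration; the null-calibration test therefore uses 4-subject
pooled replicates with 2 repetitions, where the empirical flag rate is
within the nominal band.

Classifier weights are inverted into activation patterns via
`a = Σₓ w / (wᵀ Σₓ w)` with Σₓ the feature covariance at that timepoint
(weights averaged across folds before inversion; positive pattern values
align with the suboptimal class). Patterns are masked where the 5,000-fold
bootstrap CI of the subject-mean evoked contrast excludes zero.

## Single-trial interval decoding

Three half-open analysis windows — [0, 0.75), [0.75, 1.35) and
[1.35, 2.0) s — follow the reference methods section; a variant boundary
at 0.70 s appears elsewhere in the source material and can be configured.
Per CV fold (same repeated stratified scheme), all estimation happens on
the training split: per-class xDAWN filters (generalized eigenproblem of
the class-evoked covariance against the pooled single-trial covariance,
4 unit-norm filters per class), class-evoked prototypes, and the
affine-invariant geometric mean of the training super-trial covariances.
A super-trial stacks the two filtered prototypes with the trial filtered
by the suboptimal-class filters (12×12 covariance over time, 1/(T−1); the
variant that stacks both classes' filters on the trial block would double
that block, and the 3-block layout was chosen to keep the SPD dimension at
3 × n_filters). Matrices are projected to the tangent space at the
geometric mean (upper-triangle vectorization, off-diagonals scaled by √2,
so the vector norm equals the affine-invariant geodesic distance) and
classified with a plain pooled-covariance LDA — at tangent dimension 78
and several hundred training trials per fold no shrinkage is needed.

The geometric mean uses the fixed-point iteration
`M ← M^{1/2} exp(mean log(M^{-1/2} C M^{-1/2})) M^{1/2}` from the
arithmetic-mean start, tolerance 10⁻⁸ on the Frobenius norm of the mean
log, at most 50 iterations; a residual that plateaus below 10⁻⁶ is
accepted as the floating-point floor for ill-conditioned inputs, and
anything else raises. Covariances that lose strict positive definiteness
to short crops receive a trace-proportional ridge (10⁻⁸·trace/d), which is
recorded in the construction.

## Reproducibility

Every random draw flows from one top-level seed through a stage-name CRC
derivation (`derive_seed(seed, stage, index)`), so reruns of
`robot-erp run` reproduce all JSON payloads byte-for-byte. The run
manifest records the merged configuration, the package version, the
contrast-sign convention and the explicit deviations (threshold-based
cleaning instead of ICA, zero-phase filtering, idealized electrode
coordinates).

## Problem sizes used in the shipped checks

The test suite and acceptance script run reduced but structurally faithful
problems, chosen as the smallest sizes at which each property is stable:
an 8-subject default-design study for signature recovery and interval
ordering; 200 replicate 12-subject null studies on a 32-channel × 100-
timepoint grid for family-wise error; 50 label-shuffled 4-subject
replicates for decoding-null calibration; a 4-subject, 200-trial cohort
for peak-latency recovery; 10,000 Monte-Carlo sign flips against the exact
2⁸ null for permutation-oracle equivalence. The acceptance script uses 8
subjects with 3 (temporal) and 5 (interval) CV repetitions.

## Known limitations

* The artifact stage is a statistical outlier filter, not ICA; real
  recordings with ocular artifacts will be cleaned less selectively than
  in the reference pipeline (the rejection log flags this).
* Idealized spherical coordinates approximate true electrode positions;
  CSD magnitudes scale with the (unmodelled) head radius.
* The significance rule for decoding curves is anti-conservative at high
  CV-repeat counts (see above).
* Cluster p-values and extents on request-only data are not reproduced;
  the package validates the machinery, not the dataset-specific numbers.
* BrainVision support covers multiplexed float32/int16 only.
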