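# Methods

## Signal model of the synthetic generator

The generator emulates monopolar grid sEMG during cyclic single-DOF
movements.  Each planted muscle source `s` has

* a Gaussian spatial footprint on the electrode grid,
  `w_s(x, y) = g_s · exp(−((x−c_x)² + (y−c_y)²) / 2σ_s²)`, with the center
  in continuous grid units (1 unit = 1 IED = 15 mm by default) and σ in
  IED; the grid is planar (no circumferential wrap);
* a nonnegative temporal profile over the normalized movement cycle
  (500 phase points), built from raised-cosine bursts at the dynamic phases
  plus tonic plateau components during the hold the muscle maintains.  The
  tonic components reflect postural holding activity; they also make the
  joint angle identifiable from instantaneous envelopes (without them the
  two 2 s holds would be electrically silent and indistinguishable);
* per-condition amplitude gains (`neutral` is the reference, gain 1).

The interference-pattern EMG of a source is a surrogate carrier — Gaussian
white noise band-limited to 20–450 Hz, unit variance — multiplied by the
profile sampled at the cycle phase.  A channel records the weighted sum
over sources plus: (a) independent 20–450 Hz channel noise, (b) a common
50 Hz sinusoid with per-channel amplitude scatter (0.8–1.2) and random
phase, and (c) planted bad channels replaced by low-amplitude noise
(0.3 × noise σ) uncorrelated with everything.

Joint angles are trapezoidal cycles: rise (0.75 s) → flexion hold (2 s) →
fall (0.75 s) → extension hold (2 s), targets ±30°, preceded by a rest
lead-in and ended with one extra partial rise so the last complete cycle
has a detectable end boundary.  Per-cycle timing is scaled by a 5% jitter,
per-cycle source amplitude by a 10% jitter, hold targets by a 1% ROM
jitter; the "glove" trace is the trapezoid decimated to 50 samples/s with
0.15° measurement noise.  Cycle phase for the EMG modulators runs between
consecutive ground-truth onsets (the analytic crossings of the
extension-plateau-plus-2° threshold), i.e. on exactly the axis the pipeline
reconstructs — so planted temporal modules and recovered modules share a
time base by construction.

**Noise calibration.**  `noise_snr_db` (default 15 dB) is referenced to the
source-driven power a *unit-gain* source set would produce at the most
strongly driven channel.  The noise floor is therefore a property of the
simulated acquisition chain, not of the task: finger tasks generated at
half gain face the same absolute noise and hence a ~6 dB lower effective
SNR, which is what makes their repeatability (CMC) genuinely lower than
the wrist tasks'.  An explicit `noise_sigma` can override the SNR-derived
level.

**Default study conditions** (chosen once, as a plausible recording): wrist
tasks, 20 cycles; finger tasks, 12 cycles; three wrist sources — extensor
(center ≈ (4.5, 4.5), σ 1.2), flexor (≈ (10.5, 4.0), σ 1.2), stabilizer
(≈ (7.0, 6.5), σ 1.0, temporally distinct double burst); prone-condition
gains 1.4 (extensor), 0.5 (flexor), 1.0 (stabilizer); prone spatial
displacement 0.8 IED along the ulnar–radial (column) axis; three bad
channels; per-subject source-center jitter of ±0.2 IED (inter-subject
anatomical variability, small enough to preserve the planted ≥2.5 IED
middle-finger separation margin).  Four finger-extensor centers: index
(4.0, 5.0), middle (9.0, 4.5), ring (5.8, 4.2), little (6.5, 6.0) — the
middle center is ≥2.9 IED from every other.

What the generator does **not** emulate: physiological motor-unit firing,
volume-conductor anisotropy, electrode-shift artifacts within a recording,
crosstalk beyond Gaussian spatial overlap, non-stationary noise.  Passing
recovery tests therefore show the *analysis chain* is correct and
well-calibrated for signals of this structure, not that real forearm maps
will be as clean.

## Preprocessing

Band-pass: 4th-order Butterworth 20–450 Hz applied forward–backward
(`sosfiltfilt`), which doubles the effective order and gives zero phase —
all later timing comparisons between envelope and kinematics rely on this.
Power-line removal: spectral interpolation; for each harmonic k·50 Hz
(k = 1..5) the FFT magnitudes within ±1 Hz are replaced by a linear
interpolation between the mean magnitudes of the two 1 Hz flanking bands,
phases kept.  Envelope: rectification then zero-phase 4th-order Butterworth
low-pass at 1 Hz, ringing clipped at 0 (the factorization requires
nonnegative input).

**Bad-channel detection** operates on envelopes.  Let z be the robust
z-score of log10 envelope RMS (median / 1.4826·MAD, the scale floored at
0.1 decades so a homogeneous noise floor does not inflate scores), and c
the maximum absolute correlation of a channel's envelope with its
4-connected neighbours.  A channel is flagged when

* `z < −3.5` (dead or strongly attenuated contact), or
* `z > +3.5` and `c < 0.5` (isolated high-amplitude artifact — genuine
  activity is spatially shared with neighbours), or
* `c < 0.2` and `z < −1` (low-level uncorrelated contact noise).

The correlation condition deliberately *rescues* high-amplitude channels
that agree with their neighbours: on a grid where sources cover a minority
of electrodes, genuinely active channels are extreme in amplitude but
never isolated.  A plain "extreme-amplitude OR low-correlation" rule would
mask exactly the channels carrying the signal (and, on quiet grids, every
inactive channel).  More than 50% flagged (configurable) raises a hard
error.  Detection happens once, on envelopes, and the mask is honoured by
every downstream map and statistic.

## Cycle segmentation and CMC

Cycle onsets are found by a two-state machine: while armed it tracks the
running minimum (the extension plateau) and declares an onset at the first
sample exceeding it by δ = 2°; it re-arms only after the angle has fallen δ
below its running maximum.  Cycles span consecutive onsets; partial
segments at both ends are dropped.  Flexion is mapped to increasing angle
(a polarity flag covers the opposite convention).  ROM outliers are removed
with Tukey fences (1.5·IQR).  Envelopes and angle are resampled per cycle
onto 500 equispaced phase points by linear interpolation.

CMC uses the within-day form: with C cycles, T = 500 phase points, ȳ_t the
across-cycle mean at phase t and ȳ the grand mean,

    CMC = sqrt(max(0, 1 − [Σ(y_ct − ȳ_t)²/(C(T−1))] / [Σ(y_ct − ȳ)²/(CT−1)]))

This estimator has a nonzero null value: for unrelated cycles the variance
ratio tends to 1 − 1/C, so noise-only channels sit near sqrt(1/C) (≈0.22
at C = 20), not at 0.  "Active" channels — over which median CMC is
reported — are those whose mean-envelope peak exceeds twice the grid noise
floor (median across channels of the per-channel 5th-percentile envelope).

## Module extraction

The per-task mean envelopes (bad channels dropped) are baseline-corrected —
each channel's 5th-percentile envelope is subtracted and the result clipped
at 0 — before concatenation and NMF.  Rationale: the additive noise floor
of a monopolar chain raises every channel by a temporally flat offset that
is not muscle activity; left in place it acts as a spurious flat component
that contaminates the maps and biases prone/neutral weight ratios toward 1.

NMF minimizes the Frobenius loss by coordinate descent (scikit-learn) from
random nonnegative initializations; the restart with the lowest SSE of
`n_restarts` (default 100; the studies here use 20) is kept, restart seeds
spawned from one master seed.  Scale indeterminacy is fixed by normalizing
each temporal module to unit maximum and pushing the scale into the spatial
coefficients, which makes map weights comparable across conditions.  VAF
uses the uncentered total sum of squares (SST = ΣM²), the muscle-synergy
convention; the module count is the least N (of 1..10) with VAF ≥ 0.90.
Modules are labelled by activation timing: peak phase ≥ 0.5 → extensor
(extension follows flexion within a cycle), < 0.5 → flexor; ties go to the
module with more spatial weight.  Across-condition matching takes Pearson
links between temporal modules (r > 0.7), greedily, best first, one-to-one.

## Map segmentation and comparison

Coefficient maps are histogram-equalized (rank-based mapping to [0, 1] over
unmasked cells, ties sharing mean rank), inverted, and segmented by
marker-free watershed with 4-connectivity; each catchment region around a
local maximum is then thresholded at 70% of its regional maximum, keeping
the connected component containing the peak (so clusters are 4-connected by
construction).  Regions whose maximum is below 10% of the global maximum
are discarded as noise — without a floor, flat noise regions yield spurious
clusters.  Cluster statistics: COG = weight-averaged electrode position
(IED units); overlap = shared electrodes normalized to the smaller and the
larger cluster (both reported, in %); inter-condition shift = |Δx̄| along
the ulnar–radial axis for temporally matched modules; barycenter weight =
bilinear interpolation of the map at the COG (masked cells filled from
their nearest unmasked neighbour first); weight ratio = prone/neutral
barycenter weights, guarded against a ~0 denominator.  The effect of hand
position on COG position is tested with the two-sided Wilcoxon signed-rank
test (exact null for n ≤ 25).

## Angle reconstruction

Inputs are instantaneous envelope samples (decimated to ~64 Hz — the
envelope is 1 Hz band-limited, so this is lossless in practice) from either
the proximal electrode ring (row y = 1, the conventional band placement
2 cm from the elbow crease) or one electrode per activity cluster, the
unmasked electrode nearest each COG (ties toward lower x, then lower y).
The regressor is a single-hidden-layer perceptron: 6 tanh units, linear
output, inputs z-scored with training-split statistics.  Training is
damped Gauss–Newton (Levenberg–Marquardt) on the squared error with an
analytic Jacobian; the damping factor adapts multiplicatively (÷3 on
success, ×10 on failure), and early stopping keeps the parameters with the
best error on a 30% cycle-wise validation split (patience 10).  Evaluation
is four-fold cross-validation with cycle-wise folds — samples of one cycle
never straddle the train/test boundary, which would otherwise leak through
envelope smoothness — scoring r² = 1 − SS_res/SS_tot per held-out fold.
Subset comparison: one-way ANOVA on the fold r² values followed by the
Student–Newman–Keuls stepwise post-hoc on the studentized range (ranges
that fail block their sub-ranges; harmonic-mean n for unbalanced groups).

## Numerical and design choices

* All filters zero-phase; filter settings recorded in envelope provenance.
* Degenerate inputs raise informative errors: sampling rate below the
  Nyquist requirement, empty traces, fewer than two onsets, flat waveforms
  (CMC), zero SST (VAF), all-zero channel rows (NMF), zero cluster weight
  (COG), constant targets (r²).
* ANOVA with zero between-group variation short-circuits to F = 0, p = 1
  (the F statistic is otherwise 0/0).
* Watershed dialect: marker-free on the inverted equalized map; the exact
  variant of grid-map watershed segmentation is not standardized, and this
  choice is the simplest one that partitions the grid around local maxima.
* Condition comparisons fix N = 3 modules per condition (the planted and
  selected dimensionality) instead of re-selecting 1..10 per condition;
  module-count selection is exercised where dimensionality itself is the
  question.
* Determinism: every stochastic stage (generator, NMF restarts, MLP
  initialization, fold assignment) derives its RNG from explicit seeds;
  fixed seeds give byte-identical outputs.

## Problem sizes

The bundled studies simulate 8 subjects per design — wrist: 20-cycle
flexion/extension recordings (~112 s at 2048 samples/s, 112 channels) in
two hand positions plus one zero-shift prone control; fingers: four
12-cycle single-finger tasks per subject — with NMF at 20 restarts.  One
full acceptance run (`scripts/acceptance.py`) is ~8 minutes on one CPU;
the test suite runs the same studies once (session-scoped fixtures) in
~15–20 minutes.

## Known limitations

* The generator's linearity (envelope ∝ gain) makes weight-ratio recovery
  benign; real envelope mixtures of overlapping sources add in power, not
  amplitude, and ratios would be compressed toward 1 near overlap regions.
* COG estimates from 70%-thresholded clusters quantize at the electrode
  pitch; recovered displacement medians can sit ~0.1–0.2 IED above the
  planted value for sub-IED shifts.
* The MLP reconstructs angle from instantaneous envelopes; movements whose
  angle is not a static function of muscle activation (fast dynamics,
  co-contraction) need lagged inputs, available but not enabled by default.
* Synchronization between kinematics and EMG is assumed exact (true for the
  generator); aligning real dual-stream hardware requires the shared
  auxiliary-channel hook, which is untested against hardware.
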