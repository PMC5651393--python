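# Methods

## Synthetic cohort model

Each subject's 4D series on a small grid (default 8×8×8 voxels, 3 mm, TR = 2 s,
150 frames of which the first five are equilibration dummies) is

    Y(v, t) = B + Σ_s M_s(v) · x_s(t) + γ · g(v) · m(t) + ε(v, t),

with baseline B = 1000 (so percent-signal-change scaling is well defined),
smooth Gaussian-blob source maps M_s (peak-normalized, centers on a fixed
well-separated layout so pairwise spatial correlation stays below 0.3 and ICA
is identifiable at desk scale), unit-variance source time courses x_s, a
rank-1 motion leak (γ = `motion_coupling`, g a z-scored intensity ramp along
x, m the signed sum of the translation trace), and white Gaussian noise
(`noise_sd`, default 0.2 relative to a source's peak amplitude of 1).

**State dynamics.** Sources switch among a small set of planted correlation
matrices ("states") along a semi-Markov path: at each renewal the next state
is drawn from the group's target occupancy distribution and held for a
geometric dwell time (mean `dwell_mean_tr`, default 20 TR = 40 s — in the
range of dwell times reported for resting-state dFNC, and resolvable by the
shortest tapered window, whose support is 33 frames).  The expected fraction
of frames in state m therefore equals the target occupancy; group membership
(HC vs. mTBI) changes *only* these occupancy targets (defaults 0.4/0.6 vs.
0.6/0.4 — a 20-point contrast).  Within the frames a state occupies, draws are
empirically whitened before coloring with the state's matrix square root, so
the pooled correlation over a state's frames equals the planted matrix
exactly; in the noise-free limit sample correlations match the planted
entries to machine precision.  The two default states differ in pattern, not
just amplitude: a strongly connected state with two source modules (r = 0.6
and 0.4 within, 0.25 across) and a weakly connected state (r = 0.1 in the
first module only).  Uniform matrices would make centroids constant vectors
and defeat correlation-based state matching.

**Motion and spikes.** Realignment traces are smoothed Gaussian random walks
with occasional jumps, exactly proportional to `motion_amp_mm`; rotations
reuse the translation process scaled to radians.  The leak trace is a linear
functional of the translations, so the motion regression (which includes the
raw parameters) can remove it exactly — giving the nuisance step a planted
signal it is *able* to remove, which is the property under test.  Spikes are
global intensity deviations of `spike_amp_sd` baseline SDs at Poisson-drawn
frames (`spike_rate_per_min`, default 1.5/min).

**What the generator does not emulate.** Hemodynamic convolution, spatial
autocorrelation of noise, physiological rhythms, scanner drift spectra,
realistic registration errors, or any clinical heterogeneity.  Passing tests
show the machinery recovers planted structure under fair conditions; they say
nothing about effect sizes in real cohorts.

## Preprocessing

- **DVARS** is computed on the percent-signal-change–scaled series (the
  convention of the framewise-displacement literature); frame 0 has no
  backward difference and is never flagged.  Z-scoring uses the whole-run
  DVARS mean/SD in a single pass (no iterative re-estimation); thresholds
  2.5/3.0/4.0 SD give nested spike sets by construction.
- **Nuisance regression** is OLS with intercept; the same operator serves
  voxel-wise (before gICA) and component-wise (after) use.  Derivative
  regressors are backward differences with 0 at frame 0; spike regressors are
  unit indicators.  Rank-deficient designs fall back to the pseudo-inverse
  with a warning.
- **Smoothing**: per-frame 3D Gaussian, σ_vox = FWHM/(2√(2 ln 2)·voxel size),
  reflective boundaries (preserves frame means on constant images).
- **Spike interpolation**: cubic spline through clean frames (reproduces
  cubic polynomials exactly); edge spikes are extrapolated with a warning.
- **Band-pass**: fifth-order Butterworth, [0.01, 0.15] Hz, applied
  forward-backward (zero phase) so state transitions are not shifted in time.
  Filtering removes the out-of-band part of broadband source variance, which
  lowers time-course-to-truth correlations without biasing windowed
  correlation estimates.
- Pipeline plans are fixed: only the four orderings PA–PD are constructible.

## Group ICA

Subject-level temporal PCA (to ⌈1.5·order⌉ components), concatenation, group
PCA to the model order, then spatial FastICA (fixed-point, symmetric
decorrelation).  This differs from Infomax-based tooling; the analysis depends
only on obtaining stable independent spatial sources, and FastICA is
deterministic given a seed.  Stability follows the multi-run recipe: pool the
components of `n_runs` seeded runs, cluster by 1 − |spatial correlation|
(average-linkage), return each cluster's centrotype.  Iq = mean within-cluster
minus mean between-cluster similarity (1 by convention for a single run, with
a warning); the R-index is the mean over clusters of within-cluster
dissimilarity divided by the distance to the nearest other cluster (lower is
better).  Model-order selection keeps candidates with at most two components
below Iq = 0.7 and picks the smallest order whose R-index lies within 5% of
the candidate minimum; if no candidate satisfies the Iq rule the global
R-index minimizer is returned with a warning.  Back-reconstruction is spatial
regression of each frame onto the aggregate maps.  Map signs follow positive
skewness.  Artifact flagging uses a single spectral criterion: a component is
an artifact when less than θ_lf (default 0.5) of its subject-averaged
time-course power lies below 0.10 Hz.  θ_lf is configurable; 0.5 cleanly
separates slow hemodynamic-range components from white-noise-like ones (a
flat spectrum at TR = 2 s puts 0.10/0.25 = 40% of power below the cutoff).

## dFNC states and occupancy

Window taper: rectangle of the nominal width convolved with a Gaussian
(σ = 3 TR, support ±3σ), normalized; σ → 0 recovers uniform weights.
Windowed correlations are taper-weighted Pearson correlations (no covariance
regularization, no Fisher transform by default — both noted as switchable
readings).  Windows from all subjects are pooled for clustering.  k-means
uses city-block distance with median centroid updates, k-means++-style
seeding under L1, best of several restarts; emptied clusters re-seed at the
farthest window.  The elbow rule evaluates W(k)/T — within-cluster L1
dispersion over the total dispersion about the grand median — from k = 1 to
one past the candidate range and returns the k with maximum discrete
curvature of the log curve; a flat curve falls back to the smallest k with a
warning.  (The log scale makes the curvature insensitive to the overall drop
size; evaluating k = 1 internally makes the smallest candidate eligible.)
Occupancy rates are per-subject window percentages; between-group comparisons
use unpaired t-tests (degenerate variance reports t = 0, p = 1 with a
warning), within-group state comparisons use paired t-tests.

At the default desk-scale conditions a subject contributes 113 windows whose
taper support is 33 of 145 frames — roughly 7 statistically independent
windows — so per-subject occupancy carries an irreducible error of about
7–10 percentage points even when clustering from the true time courses.
Group-mean occupancy is recovered to within a few points, and the planted
20-point group contrast is detected reliably at 48 subjects per group; those
are the guarantees the tests assert.

## Pipeline statistics and classification

Motion covariates: TRN and ROT are temporal means of the summed absolute
backward differences of translations (mm) and rotations (radians — no
sphere-radius conversion), computed on dummy-trimmed traces; spk is the spike
count at the configured threshold.  Outlier exclusion removes subjects above
mean + 3 SD on at least two of {TRN, ROT, spk} together with their matched
pair partners.  Pipeline MANOVA uses Wilks Λ = det(W)/det(W+Β) with the
Bartlett χ² approximation (df = p(g−1)); singular within-group scatter is
ridge-shrunk with a warning.  Per-edge ANOVAs are reported uncorrected, with
Benjamini–Hochberg adjustment available.  Covariate strength is the per-edge
|β| from an OLS including diagnosis, gender, age, TRN, ROT and spk
(continuous covariates standardized), compared across pipelines by ANOVA on
the per-edge |β| distributions.

The classifier is a linear least-squares SVM (squared slacks, equality
constraints, C = 0.01): training solves one symmetric (n+1) linear system in
the dual.  Features are the concatenated per-state subject mean connectivity
vectors; a state a subject never visits is imputed to the cohort mean and
flagged; occupancy percentages can be appended (off by default in the
library, used by the driver example features where noted).  Covariate
adjustment (everything except diagnosis) is refit inside every training fold
— fully nested, no leakage from held-out subjects.  LOOCV decision values are
centered at each fold's mean training decision before pooling for AUC:
without this, the bias term tracks the leave-one-out class imbalance and
pushes the null AUC well below 0.5; with it, permuted-label AUC centers near
0.5 (a small residual pessimism from self-exclusion remains at very small n).
Nested selection runs an inner LOOCV per configuration on the n−1 remaining
subjects, picks the max-AUC configuration (ties to the first in enumeration
order), and lets it classify the held-out subject; the n × n_configs AUC grid
and per-configuration selection counts are retained.  The significance null
permutes labels B times and pools per-configuration mean AUCs (an
alternative that bootstraps the observed grid around chance is available);
configurations above the 95th percentile are flagged.

## Driver and reproducibility

`run_all` executes preprocessing + gICA once per (pipeline, threshold, order)
combination and reuses the cleaned time courses for every window size; the
state count is chosen by the elbow rule on the first configuration and held
fixed so occupancies are comparable across the grid, and states are aligned
to a reference model per pair dimensionality.  All randomness descends from
one seed through named substreams; reports carry a SHA-256 hash of their own
JSON content, and a repeated run reproduces it bit for bit.  Problem sizes in
the test-suite and acceptance script (8³ grids, 5 sources, 12–48 pairs, 1–2
ICA runs, 10–20 replicates) were chosen so the full chain, including the
108-configuration driver run, completes in minutes on one CPU.

## Known limitations

- FastICA replaces Infomax; component *values* are not comparable to
  GIFT-derived analyses, only the pipeline-level behavior is.
- The artifact criterion is a single spectral threshold; no expert review or
  anatomical overlap scoring is emulated (ground-truth labels substitute).
- Per-subject occupancy precision is window-limited (above); short scans
  cannot be fixed by any clustering choice.
- The permutation null at small B is noisy (a warning fires below B = 100).
- Geometric dwell times are an assumption; real state dynamics are not
  characterized by a single dwell distribution.
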