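# Methods

This note documents the models, conventions, and design choices behind
`synchnet`, and what the synthetic validation does and does not establish.

## Signal model and synthetic cohorts

Each simulated subject's cortical activity lives at `n_nodes` seed sources
of a spherical head model. Per frequency band *b* (delta 1–4, theta 4–8,
alpha 8–12, low beta 12–18, high beta 18–30, gamma 30–55 Hz; half-open
`[lo, hi)` edges so the six bands tile 1–55 Hz), node *i* receives

    x_i^(b) = amp_b · ( sqrt(1 − c_b) · e_i + sqrt(c_b) · s )

with `e_i` node-specific and `s` a shared narrowband driver (white noise
band-passed with the same zero-phase 3rd-order Butterworth used in the
analysis, normalized to unit variance). The coupling level `c_b ∈ [0, 1]`
controls expected pairwise phase locking monotonically while leaving the
band's amplitude unchanged, so group contrasts can be confined to a single
band by construction. Drivers are noise, not sinusoids: phases are
non-degenerate and PLV < 1 generically.

Band amplitudes default to an eyes-closed-like resting spectrum
(alpha-dominant: delta 0.95, theta 0.65, alpha 1.45, low beta 0.5, high
beta 0.4, gamma 0.3 in source units that project to a scalp RMS of a few
µV). Alpha dominance is what guarantees clean epochs pass the
theta/alpha < 1 drowsiness screen with a wide margin, and the overall scale
keeps clean scalp peaks far below the ±75 µV artifact criterion (worst-case
clean peaks ≈ 30 µV after EOG regression).

**Forward model.** Sensors sit quasi-uniformly on the unit sphere
(Fibonacci lattice). Sources take random interior positions with radius in
[0.3, 0.9], additionally respecting a 0.25-radius electrode standoff (the
scalp/skull gap); without the standoff a source can land arbitrarily close
to one sensor and produce a single "hot" channel whose background peaks
cross the artifact threshold. Each source carries a fixed random dipole
orientation — cortical dipole orientation follows local folding rather than
the radius vector — and the gain is the infinite-homogeneous-medium dipole
projection with an inverse-square distance law,
`g_ms = cos∠(r_m − r_s, d_s) / ‖r_m − r_s‖²`, globally scaled to mean
column norm 1. Column norms decrease with depth, which is the property the
depth-weighted inverse must compensate. Node seeds are a greedy
farthest-point subset of the sources. Random orientations (rather than
radial) are also what keeps neighbouring sources' scalp patterns
decorrelated enough for single-source localization; radial orientations cap
the correct-node rate near 60 %.

**Corruption with ground truth.** On a fixed 2-s segment grid the generator
flags `round(fraction × n_segments)` segments per kind, disjointly:
*artifacts* add a single-sample ±100 µV deviation (sign-matched to the
carrier so the post-filter peak always exceeds 75 µV) on one random
channel; *drowsy* segments emulate sleep onset by removing 70 % of the
in-segment alpha band and adding theta noise at 1× the recording's alpha
RMS (Hann-tapered edges), driving the epoch's theta/alpha power ratio to
≈ 5–9 while adding only a few µV of amplitude. Both manipulations are
recorded per subject, so screening can be checked for *exact* set equality
against the truth. EOG contamination uses a 1–5 Hz drift plus blink bumps,
entering the scalp through an exponentially decaying frontal topography
(scale 0.5 sphere radii); blinks dominate raw peaks (~65 µV) but are
removed by the regression step before epoching.

## Screening conventions

Pipeline order is fixed: average reference (EOG excluded) → 1 Hz zero-phase
high-pass → EOG regression (least squares with intercept; residuals exactly
uncorrelated with each regressor; constant regressors skipped with a
warning) → epoching from sample 0 (trailing remainder discarded) →
amplitude rejection → drowsiness rejection → first-`n` selection. Epoch
length is defined in seconds (samples = `round(2·fs)`), not a hard-coded
sample count. Thresholds are strict inequalities ("exceeding"). The
drowsiness ratio uses the channel-averaged Welch PSD (1-s Hann segments,
50 % overlap), integrating theta and alpha bin-wise; the relative-power
denominator cancels in the ratio. Zero alpha power counts as drowsy (ratio
+∞) with a warning. Selection keeps the earliest survivors: deterministic
and reproducible.

## Inverse conventions

Diagonal noise covariance only: per-sensor variances pooled over the kept
epochs' samples; a constant sensor raises a degenerate-covariance error.
The estimator minimizes `‖C^(−1/2)(M − LJ)‖² + λ²‖R^(−1/2)J‖²` with
`R = diag(‖l_i‖^(−2γ))` scaled so `trace(L R Lᵀ) = trace(C)` and
`λ² = 1/SNR²` (SNR = 3 by default; both exposed in config). The kernel is
computed in sensor space, `K = R Lᵀ (L R Lᵀ + λ²C)⁻¹`, and equals the
normal-equations solution exactly (tested to 1e−8 against a brute-force
oracle). Orientations are fixed scalars; the node series is the seed
source's own row of `K M` (not a parcel mean).

The depth exponent defaults to **γ = 1** (full column-norm normalization).
On this geometry γ = 0.5 leaves deep sources systematically mislocalized
(≈ 74 % correct-node rate in noiseless single-source simulations, vs
93–96 % at γ = 1); since the package's contract is reliable seed-level
recovery, the stronger exponent is the default and 0.5 remains available in
config. With λ² → 0 and γ = 0 on a square full-rank system the kernel
reproduces the exact matrix inverse.

## Connectivity conventions

PLV is computed *within* each 2-s epoch over time samples, then averaged
across epochs (the trial-locked definition does not apply to resting data).
Phases come from the analytic signal of the band-passed series; 10 % of
samples are discarded at each epoch edge to suppress quadrature edge
artifacts (configurable). Zero-lag differences are not excluded —
volume-conduction-driven zero-phase coupling inflates PLV by design here,
matching the estimator being modelled; imaginary-coherence variants are out
of scope. Phasor cross-products are accumulated in single precision (the
estimator's sampling noise is orders of magnitude larger), averages in
double; matrices are symmetrized, clipped to [0, 1], zero-diagonal, and
validated on construction.

**Noise floor.** A band of width *B* observed for *T* seconds carries
≈ *BT* independent phase samples, so the no-coupling PLV floor is the
Rayleigh resultant `sqrt(π/(4·BT))` — for theta in 2-s epochs ≈ 0.31,
*regardless of sampling rate*. Uncoupled-source tests therefore assert the
floor (< 0.4) plus strict monotonicity in the coupling level, not an
arbitrarily small value; empirical matrices at realistic couplings
(mean PLV ≈ 0.33–0.36 in theta) sit in the same range as published
source-space PLV networks.

## Graph-metric conventions

Weighted throughout; no thresholding or binarization. Strength is the row
sum, reported globally as the across-node *mean* (a complete graph of
uniform weight *w* has global strength `(N−1)w`, and PLV-scale weights give
magnitudes comparable to published tables). Clustering follows the Onnela
geometric-mean convention with max-normalized weights; `C_i = 0` for nodes
with fewer than two links; global CC is the nodal mean. Distances use link
lengths `l = 1/w` with Dijkstra (scipy.sparse.csgraph); brute-force
Floyd–Warshall and direct triple-sum oracles verify both exactly in the
tests. Path length averages finite off-diagonal distances; efficiency
averages `1/d` with `1/∞ = 0`; a fully disconnected matrix is an error.

## Statistics conventions

Group comparison is a per-measure ANCOVA `value ~ group + covariate`
(statsmodels OLS, type-II sums of squares — identical to type III here as
no interaction is modelled), with `partial η² = SS_group/(SS_group +
SS_resid)`; the sums of squares match direct matrix least squares to 1e−8.
Families: 24 global tests (0.05/24 = 0.002083) and 148 nodal tests
(0.05/148 = 0.000338), two-tailed. Post-hoc contrasts come from the
full-model coefficients, Bonferroni-multiplied by the number of pairs
(capped at 1). Partial Pearson correlation residualizes both variables on
the covariates (with intercept) and uses the t transform with
`df = n − 2 − k`; the CI is a seeded percentile bootstrap over subjects
(simple random resampling with replacement, default 5,000 resamples, 95 %),
with residualization repeated inside each resample. Degenerate resample
designs fall back to pseudo-inverse; resamples with undefined correlation
are dropped from the percentile. Calibration is verified by simulation:
type-I error at nominal α within [0.03, 0.07] over 1,000 null cohorts, and
CI coverage for ρ = 0.5 at n = 34 within 95 % ± 3 % over 500 replications.

## Problem sizes of the validation study

The directional two-group study runs at deliberately scaled sizes chosen as
this package's desk-scale validation conditions: 20 subjects per group,
60 s per subject at **250 Hz** sampling, 62 sensors, 148 sources with all
148 as node seeds. 250 Hz keeps Nyquist (125 Hz) far above the highest band
edge (55 Hz); because PLV estimator variance is governed by bandwidth ×
time rather than sample count, the lower rate costs no statistical power.
The coupling contrast (theta c = 0.30 vs 0.15, all other bands at the 0.20
resting baseline) produces the expected pattern — higher theta strength,
clustering and efficiency, lower path length, all far beyond the 0.05/24
threshold (partial η² ≈ 0.9), with no other band flagged — in essentially
every seeded replicate.

## What the synthetic validation does and does not show

It shows the *pipeline* is correct and well calibrated: every stage recovers
known ground truth (injected corruption exactly; coupling monotonically;
single sources at ≥ 90 %; null statistics at nominal rates). It does not
show that real clinical EEG exhibits these effects: the generator has no
realistic cortical geometry or tissue conductivities, no 1/f background or
non-stationarity, no muscle/line-noise artifact taxonomy, and
within-group heterogeneity comes only from estimation noise, so empirical
effect sizes (η² ≈ 0.9) are far larger than anything achievable with real
between-subject variability. Band-edge leakage of the 3rd-order filters
(adjacent bands share edges at 4, 8, 12, 18, 30 Hz) produces a small,
systematic cross-band coupling visible at very large n but negligible
relative to the family thresholds at these sizes.

## Degenerate inputs and numerical choices

All-zero signals have undefined phase (error naming the node); constant
sensors make the noise covariance degenerate (error); fewer surviving
epochs than requested raises an insufficient-data error naming the subject;
pipeline stages wrap failures with the stage name. Symmetry checks use
1e−10 tolerances; PLV matrices are clipped to [0, 1] after
single-precision accumulation; the bootstrap and every simulation are
driven by explicit integer seeds, and identical cohort specifications
reproduce bit-identical recordings.
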