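# Methods

This note documents the models behind `mstates`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not establish about real infant EEG.

## Signal model and preprocessing

The unit of analysis is average-referenced, band-limited (1–40 Hz in the
intended acquisition pipeline) multichannel EEG in microvolts. Upstream
artifact correction (wavelet thresholding, muscle ICA, line-noise removal,
bad-channel interpolation) is assumed done by a dedicated preprocessing
pipeline and is out of scope here; `mstates` picks up at the epoch level:

- **Epoching**: consecutive non-overlapping 2-s windows; a trailing partial
  window is discarded.
- **Amplitude rejection**: an epoch is dropped when any channel's absolute
  voltage exceeds 150 µV at any sample. The comparison is strict, so a peak
  of exactly 150 µV survives. A plausible alternative reading of a
  "±150 µV amplitude change" is within-epoch peak-to-peak change; absolute
  voltage was adopted because the data reaching this stage are already
  high-pass filtered (near-zero mean), where the two readings differ by at
  most a factor ~2, and the absolute rule is the simpler contract to test.
- **Average reference**: subtract the instantaneous channel mean; idempotent
  and required before any GFP or spatial-correlation computation.
- **Retention gate**: a recording enters group analysis only with strictly
  more than 15 clean segments, i.e. more than 30 s of data.

Channel positions are unit vectors on the sensor sphere. They matter only
for simulation, canonical templates and plotting — GFP and spatial
correlations are reference- and position-free — so a missing montage is
replaced by a deterministic generic spherical layout with a logged warning
rather than an error.

## Microstate segmentation

**GFP and peak maps.** GFP(t) is the spatial standard deviation of the
average-referenced map (divisor C, not C−1). Local GFP maxima carry the
highest topographic signal-to-noise, so only maps at interior strict maxima
are clustered. Peaks are thinned greedily from the highest GFP downward to
a minimum spacing of 10 ms (ties broken toward the earlier sample), and at
most 1000 peaks per participant enter clustering; when more survive, a
seeded uniform subsample is taken (the thinning order makes the kept set
well-defined; the subsample rule is this package's choice, as any reduction
scheme would be).

**Modified k-means.** Cluster "centers" are unit-norm topographies a_k; a
map v_t is assigned by maximal squared projection (a_kᵀ v_t)², and the
update step replaces a_k with the principal eigenvector of the scatter
matrix of its members. Squaring makes both steps invariant to the sign of
v_t and of a_k — a topography and its polarity-reversed twin are one
microstate, as expected for oscillatory generators. The residual noise
variance

    σ̂² = Σ_t (‖v_t‖² − (a_{L(t)}ᵀ v_t)²) / (T (C − 1))

is non-increasing across iterations; a run stops when its relative change
drops below 1e−7 (or at 1000 iterations). Fifty stochastic restarts are
run and the restart with minimal σ̂² wins — equivalently, maximal explained
variance on the peak maps; the selection functional is this package's
choice. Empty clusters are re-seeded from the currently worst-fit map.
Ties in the assignment break to the lowest class index. Singleton clusters
use the member map itself as prototype. Prototype polarity is fixed for
reporting by making the largest-|value| channel positive.

*Initialization.* Even-numbered restarts seed the prototypes with K
distinct randomly chosen peak maps (the classical scheme); odd-numbered
restarts use isotropic random zero-mean unit directions. The pure
data-point scheme restricts the initial prototypes to the span of observed
maps, and on small peak sets this can exclude the global optimum's basin
entirely — we observed 5-map instances where every one of the 20 possible
data-point initializations converged to a local minimum while a third of
random directions found the global one. Alternating the two schemes keeps
the fast convergence of data-point seeding on realistic peak sets and
restores global reliability on hard ones.

**Fit criteria.** Global explained variance
GEV = Σ_t (GFP_t·r_t)²/Σ_t GFP_t², with r_t the spatial correlation between
map t and its assigned prototype; per-class terms partition the total. The
predictive residual criterion CV = σ̂²·((C−1)/(C−1−K))² penalizes K and is
minimized over a scan of K = 2…8; a forced fixed K (e.g. 4) reproduces the
sensitivity mode. The CV exponent follows the standard microstate-toolbox
convention. Group-level clustering pools the per-participant peak maps of
one visit and is performed for each visit separately, since the identity
and number of classes can change over development; a per-participant
meta-clustering mode was considered and rejected as the default because
pooled peaks are the straightforward reading of "N peaks per participant
were included in the segmentation".

## Backfitting, smoothing, statistics

Every sample of every retained epoch is labeled by the prototype of maximal
absolute spatial correlation (ties to the lowest index, which also handles
the measure-zero case of an all-zero map). The full |corr| matrix is kept.

**Temporal smoothing.** Sample-wise labeling under noise produces spurious
sub-30 ms segments. Within each epoch, the shortest sub-threshold run
(ties: earliest) is rejected: each of its samples excludes its current
label and takes the best not-yet-rejected class by global map dissimilarity
GMD = √(2(1−|corr|)) — for stored absolute correlations the same ordering
as next-highest |corr|. When some sample exhausts all classes the run is
merged into the neighboring run with the higher boundary correlation. Runs
are recomputed and the process repeats until no sub-threshold run remains;
a run spanning its whole epoch is left as is. Shortest-first processing is
this package's choice (the order is not standardized anywhere).

**Statistics.** Runs never span epoch boundaries — epochs are discontinuous
excerpts — and boundary-truncated runs are counted, which makes

    occurrence_k × duration_k / 1000 = coverage_k

an exact identity (duration = mean run length in ms, occurrence = runs per
second of labeled data, coverage = fraction of samples). The
exclude-truncated-runs variant would break the identity and is available
behind a flag. A class that never occurs has missing duration and zero
occurrence/coverage. GEV per class is computed over all samples, not only
peaks.

**Canonical labels.** Recovered maps are matched one-to-one to reference
maps by Hungarian assignment on 1 − |corr| costs. The shipped A–G templates
are synthetic dipolar idealizations of the canonical family descriptions
(A right-frontal→left-posterior, B its mirror image, C anterior–posterior,
D fronto-central→occipital, E centro-parietal radial, F/G left/right
lateralized); matching against them is advisory labeling, standing in for
visual classification, not a validated atlas.

**Outlier trimming.** Within each (cohort, visit, class, feature) group,
values more than z = 3 sample standard deviations from the group mean
(computed including the candidate) are removed — only the offending value,
not the whole subject-visit record, the more conservative reading of
trimming "data points". Constant groups remove nothing; groups smaller
than 3 are skipped with a warning.

## Trajectory models

Each feature/class response is modeled as

    y_ij = β0 + β1·age_ij + β2·g(age_ij) + β3·sex_i + β4·segments_ij + u_i + ε_ij

with u_i ~ N(0, σ_u²), ε_ij ~ N(0, σ_e²), age in months, sex coded
0 = female / 1 = male, and the retained-segment count as a covariate of no
interest. g is absent (linear), age² (quadratic, raw months², with an
optional centering flag off by default) or ln(age) (natural log).

**Fitting** is maximum likelihood, not REML, so log-likelihoods are
comparable across fixed-effect specifications: the marginal likelihood with
per-subject covariance σ_u²J + σ_e²I is profiled over λ = σ_u²/σ_e² (GLS β
and closed-form σ_e² at each λ; Woodbury reduces the whitening to per-group
mean corrections), and λ is found by bounded 1-D minimization on the log
scale. A boundary optimum clamps σ_u² to 0 (the fit degenerates to OLS,
exactly so with one observation per subject). Standard errors are Wald
from σ_e²(XᵀΣ⁻¹X)⁻¹ with normal-theory p-values — the reference
distribution for mixed-model fixed effects is not settled, and Wald-z is
the assumption-lightest choice; p-values near the 0.05 boundary in small
samples should be read accordingly. No multiple-testing correction is
applied. BIC = −2·loglik + p·ln(n_obs) with p counting fixed effects plus
the two variance parameters.

**Age-model selection**: the nonlinear model is adopted only when the
linear model's BIC exceeds it by at least 6 points (inclusive); if both
nonlinear candidates qualify the lower BIC wins; otherwise linear is
retained — a deliberately conservative gate.

**Effect sizes**: marginal R² = var(Xβ̂)/(var(Xβ̂) + σ_u² + σ_e²);
f² = (R²_full − R²_reduced)/(1 − R²_full) by refitting without one
predictor (dropping "age" removes the linear term while keeping any
nonlinear term). Marginal rather than conditional R² is used throughout.
Labels small/medium/large at 0.02/0.15/0.35.

## Synthetic ground truth

The EEG generator plants K dipolar maps (channel position · random
orientation, demeaned, unit norm, pairwise |corr| ≤ 0.7 by rejection
sampling with greedy-set restarts) on a golden-spiral montage biased to the
upper hemisphere. The state sequence is semi-Markov with geometric dwell
times (memoryless — the simplest law consistent with a mean-duration
parameterization; a gamma option is a possible extension) and uniform
transitions over the other K−1 states. Sample t is
amplitude·|sin(2πf·t/fs)|·map[label(t)] plus spatially white Gaussian
noise, average-referenced and scaled so that RMS(signal)/RMS(noise) equals
the requested SNR. Defaults: 64 channels, 500 Hz, 10 Hz envelope, 15 µV
amplitude, 80 ms mean dwell, SNR 4, 120 s per subject — enough for ~2400
GFP peaks (subsampled to 1000) while keeping tests at seconds scale.

The longitudinal generator draws visit ages from the four-visit infancy
schedule — means (SD) 3.74 (0.879), 8.72 (1.49), 14.1 (1.24) and
21.5 (1.20) months — with truncated-Gaussian retained-segment counts in
16–91 and independent missingness. All generators are bit-reproducible
given (seed, parameters).

**What the generator does not emulate**: 1/f background spectra, alpha
reactivity, artifacts, volume-conduction forward models, spatially
correlated noise, age-varying topographies within a visit, or informative
missingness. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated model, not robustness to real
infant EEG's full complexity.

## The smoothing floor and "recovered" dynamics

Mean durations computed from smoothed labels are not estimates of the raw
mean dwell parameter. Under a geometric dwell law with an 80 ms mean at
500 Hz, ~30% of dwells are shorter than 30 ms; smoothing absorbs them into
neighboring runs for recovered and perfectly known labels alike (e.g. a
planted sequence with raw mean run length 75.6 ms reads 114.5 ms after
smoothing). Recovery is therefore assessed against the planted label
sequence processed by the same smoothing operator — what an error-free
labeler would report. Under the default conditions the pipeline matches
that reference within ~1% per class at SNR 4; between-condition contrasts
computed under a fixed smoothing threshold remain interpretable, but
absolute durations always carry the threshold as part of their definition.

## Problem sizes in the validation suite

The acceptance checks run at: 120 s × 64 channels × 500 Hz per synthetic
subject (1000 peaks); 10 seeds for dynamics recovery; 20 seeds for the
K = 2…8 scan; 50 tiny instances for the exhaustive-enumeration oracle
(≤ 7 maps, 4 channels, K = 2, all 2^T labelings); 100 replicates per
scenario of 300 subjects × 4 visits (15% missingness) for mixed-model
selection and recovery (60 in the standalone script); a 3-subject toy for
the likelihood oracle; and two full pipeline runs (4 subjects × 2 visits)
for byte-level determinism. These sizes were chosen so the whole suite
completes in a few minutes on one CPU while keeping every Monte Carlo
margin wide relative to its threshold.

## Known limitations

- Backfitting assigns every sample to some class; there is no "none"
  state, so low-GFP stretches inherit labels from noise (mitigated but not
  removed by smoothing).
- The CV criterion presumes C − 1 > K and its K-penalty is mild for large
  C; on low-density montages the scan can be shallow around the optimum.
- Canonical A–G matching is a geometric idealization; on infant montages
  the visual classes are themselves debated.
- The trajectory stage models one feature/class at a time with a random
  intercept only; random age slopes and cross-feature joint models are out
  of scope.
- Transition-probability/syntax analyses are not implemented.
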