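# Methods

## Scope and data model

The package computes, for each subject of a cohort: per-epoch
leakage-corrected amplitude envelope correlation (AEC-c) matrices from
band-limited region time series; one maximum-connectivity spanning tree per
epoch; the global tree metrics leaf fraction (LF), normalized diameter (D)
and tree hierarchy (TH), averaged across epochs per band; and a cohort-level
statistical battery against a scalar plasma biomarker. Everything upstream
of region time series (acquisition, artifact handling, source
reconstruction) is out of scope: the synthetic generator produces
region-level signals directly.

The canonical containers are `EpochedTimeSeries` (region × epoch × sample
with sampling rate), `ConnectivityMatrix` (symmetric, zero diagonal, one per
epoch and band), `SpanningTree` (N nodes, N−1 weighted edges) and a pandas
cohort table (one row per subject; `biomarker`, `group`, and
`{band}_{metric}` columns).

## Filtering and envelopes

Band-pass filtering uses a 450th-order FIR designed with a Hann window and
applied forward-backward (`scipy.signal.filtfilt`), so the effective
response is zero-phase with the squared one-pass magnitude. Epochs are
mirror-padded with up to 2000 samples per edge before filtering; when an
epoch is too short the pad is truncated to the available length and logged.
Mirror padding is used because epochs are independent segments with no
flanking data to pad with.

At 1000 Hz the two-pass gain of this design is 1.000 at each band's center
and < 1e−8 at 40 Hz for the alpha band; near the band edges it rolls off
(e.g. ≈ 0.96 at 10 Hz in the 8–13 Hz band). The order and padding are
overridable per call and echoed to the log. Envelopes are the magnitude of
the analytic (Hilbert) signal, computed per epoch with no edge trimming, no
log transform and no envelope low-pass.

## AEC-c

For a pair of band-limited, per-epoch demeaned signals (x, y):
orthogonalize y on x by removing the zero-lag least-squares projection
(`y − (cov(x,y)/var(x))·x`, so corr(residual, x) = 0 exactly), correlate
the Hilbert envelope of the residual with the envelope of x, repeat in the
other direction, and average the two signed correlations. No absolute value
is taken; the tree stage operates on ranks, and negative estimates rank
below positive ones. A pair whose residual is numerically zero (collinear
signals, e.g. duplicated regions) gets AEC-c = 0 — the weakest possible
link — with a warning, so degenerate inputs cannot abort a batch run.
`connectivity_stack` is an exactly equivalent vectorized implementation
(verified to 1e−10 against the scalar path) used for whole-epoch batches.

## Spanning trees and metrics

Kruskal's algorithm runs on edges sorted by descending AEC-c (equivalent to
ascending reciprocal weight for positive entries), with lexicographic
(i, j) order as a deterministic tie-break; non-positive weights sort below
all positive weights automatically and are only used when needed to span
the graph. Edges keep their original AEC-c weights.

Metrics for a tree on N nodes with m = N−1 edges:

* L = number of degree-1 nodes; LF = L/m ∈ [2/m, 1];
* d = largest hop distance; D = d/m ∈ [2/m, 1];
* BC(v) = fraction of unordered node pairs (endpoints excluded) whose
  unique tree path passes through v, i.e. betweenness normalized by
  (N−1)(N−2)/2; BC_max = max over nodes;
* TH = L/(2·m·BC_max); equal to 0.5 for a star exactly under this
  normalization, approaching 0 for a long path.

Per-subject, per-band values are the arithmetic means of the per-epoch
metrics. Tests anchor these against closed forms (star, path, a 5-node
Y-tree), exhaustive spanning-tree enumeration via Prüfer sequences for
N ≤ 7, a pair-enumeration betweenness oracle, and
`networkx.maximum_spanning_tree`.

## Statistics

* Pearson correlations with two-tailed p from the t-distribution (df n−2).
* Benjamini–Hochberg step-up FDR at q = 0.1. Two families exactly:
  the 9 whole-sample tests (3 bands × 3 metrics) and the 18 per-group tests
  pooled across both groups. The reported "threshold" is the largest raw p
  in the rejection set. Demographic screens stay outside both families.
* Group location tests: pooled-variance Student t (two-tailed), from
  summaries or raw samples; 2×2 Pearson χ² without continuity correction.
* Between-group correlation comparison: two-sample Fisher r-to-z,
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), reported one-tailed as
  p = 1 − Φ(|z|). The one-tailed convention was adopted because it
  reproduces the reference column of published values at n = 54/22 where
  the two-tailed variant does not; it is an inference about that analysis,
  not a stated formula.
* TH is non-monotone in topology (low for both extreme trees), so where a
  group's TH test is significant the battery adds the TH–LF correlation in
  that group and band to orient the direction of the shift.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture. Per band, region i emits `envelope_i(t) · carrier_i(t)`:

* **Envelopes.** `z = √c·z_shared + √(1−c)·z_own`, where each z is
  standardized smoothed rectified Gaussian noise, low-passed at half the
  band's lower edge (e.g. 4 Hz for alpha) so the modulation is slow relative
  to the carrier (Bedrosian regime). The envelope is `1 + 0.25·z`, floored
  at 0.05. By construction the planted envelope correlation between any two
  regions equals the coupling c; the generator can return these ground-truth
  envelopes as the oracle for AEC-c tests.
* **Carriers.** A cosine with frequency drawn uniformly from the band's
  interior (10% edge margin) and uniform random phase, independently per
  region and epoch — zero-lag phase coupling is negligible while amplitude
  coupling is planted, the regime orthogonalization must tolerate without
  destroying.
* **Cohort.** Couplings are Normal(coupling_base, coupling_sd) clipped to
  [0, 0.9]; the biomarker is
  `biomarker_mean + effect_size·(c_s − coupling_base) + Normal(0, noise_sd)`,
  floored at 1 pg/ml. Group labels go to the first `n_fhpos` subjects.
  All draws descend from one `SeedSequence(seed)`, so a spec is a pure
  recipe: same seed, bitwise-identical cohort.

Defaults are study-scale: 76 subjects (54/22 groups), 80 regions, 30 epochs
of 4096 samples at 1000 Hz, theta/alpha/beta bands, biomarker mean 381.7
and noise SD 150 pg/ml, coupling 0.35 ± 0.15, and effect size 577.35 pg/ml
per unit coupling — the value that plants a biomarker–coupling correlation
of 0.5 via e = σ_n·ρ/(σ_c·√(1−ρ²)). `CohortSpec.test_profile()` is the
scaled-down profile used throughout the tests (20 subjects, 10 regions,
10 epochs of 1024 samples at 250 Hz).

**What the generator does not emulate:** 1/f spectra, narrow-band power
differences between subjects, spatially structured (distance-dependent)
connectivity, heterogeneous per-pair coupling, head movement or sensor
noise. Passing tests therefore demonstrate that the estimator chain is
correct and calibrated under planted ground truth, not that any specific
empirical claim about real MEG cohorts holds.

### Why coupling moves tree topology

All pairs share one planted coupling c, and MSTs depend only on weight
ranks, so the effect of c on topology is indirect: writing the sample
envelope correlation as
`r̂_ij ≈ c + √(c(1−c))(a_i + a_j) + (1−c)·b_ij` (a_i = sampling covariance
of region i's idiosyncratic envelope with the shared one, b_ij pairwise
noise), the node-additive term grows as √(c/(1−c)) relative to the pair
noise. Higher coupling therefore concentrates strong edges on a few
sample-level "hub" regions and raises the leaf fraction of the tree. Pilot
simulation of this mechanism guided the end-to-end test profile: 76
subjects, 12 regions, 25 alpha epochs of 256 samples at 125 Hz, where the
induced corr(coupling, LF) ≈ 0.7 gives a directional test power near 0.9
at the planted biomarker–coupling correlation of 0.5.

## Numerical choices and degenerate inputs

* Ties in Kruskal: stable lexicographic (i, j) secondary key; an all-zero
  matrix is still spanned (deterministically) by zero-weight edges.
* Non-finite matrices, bands at or above Nyquist, epochs shorter than the
  filter order, zero-variance regressors, empty p-value families, zero
  χ² margins and |r| = 1 in the Fisher comparison all raise `ValueError`
  with the offending field named.
* Collinear AEC-c pairs: value 0 plus `RuntimeWarning` (see above).
* BH adjusted values come from `statsmodels.multipletests` and are
  cross-checked in tests against a brute-force step-up implementation on
  1000 random p-vectors.
* Monte-Carlo test bounds were derived from the generator itself before
  freezing: at 120 s of alpha-band signal the null AEC-c has r-s.e. ≈ 0.03
  (envelope bandwidth 4 Hz), so the null tests assert mean |AEC-c| < 0.05
  and 95th percentile < 0.08; planted-coupling recovery is asserted within
  ±0.1 of the stored-envelope oracle.

## Problem sizes used by the test suite

Unit and property tests run at reduced scale (trees up to N = 20,
enumeration oracles at N ≤ 7, pairwise Monte-Carlo at 120 s, tiny pipeline
cohorts); the end-to-end recovery simulation uses 100 replicate cohorts of
76 subjects at the reduced profile above. The study-scale spec (80 regions,
30 epochs, 1000 Hz) remains available through configuration and the CLI.

## Known limitations

* The per-band FIR keeps the 450th-order convention of the broadband stage
  it mirrors; narrow bands at 1000 Hz have visible edge droop (above).
  Raise the order via the `order` argument if edge-of-band fidelity
  matters.
* Envelopes are not downsampled or log-transformed before correlation;
  published AEC-c variants differ on this and the reference analysis does
  not specify.
* The epoch nominally described as "four seconds" is 4096 samples at
  1000 Hz (4.096 s); `epoch_samples` is taken literally.
* The battery reports no covariate-adjusted (partial) correlations, and
  node-level (regional hub) statistics are out of scope.
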