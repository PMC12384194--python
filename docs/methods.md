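# Methods

## Signal model and scope

Each voxel of a resting-state BOLD acquisition is treated as a
uniformly sampled scalar series u(1..N) with sampling interval TR
(study-like data: N = 245 after discarding 5 of 250 volumes, TR = 2 s).
The package quantifies two aspects of temporal structure per voxel —
irregularity (fuzzy approximate and sample entropy) and long-range
correlation (Hurst exponent by dispersional analysis) — then aggregates
over an intensity-derived brain mask and performs two-group inference
on the whole-brain summaries.  Spatial preprocessing (realignment,
skull-stripping, normalisation) is out of scope: inputs are assumed
already realigned, and only the temporal chain is applied here.

## Fuzzy entropies

Templates of length m (delay tau) are compared by Chebyshev distance
and a mirrored-quadratic similarity kernel mu(x) with x = d/r:
(2−x²)/2 on [0,1], (2−x)²/2 on (1,2], exactly 0 beyond 2.  The kernel
is continuous, non-increasing, mu(0)=1, mu(1)=0.5.  The tolerance is
r = k·SD(u) with the sample SD (denominator N−1); k defaults to 0.25.

*fApEn.*  Templates are baseline-subtracted (each window minus its own
mean); there are N−(m−1)tau templates of length m.  The per-template
mean similarity C_i includes the self-match j = i, so C_i > 0 and
ln C_i is always defined.  Phi^m is the mean of ln C_i and
fApEn = Phi^m − Phi^(m+1).

*fSampEn.*  Templates are raw; the template index runs i = 1..N−m·tau
for **both** lengths m and m+1, so numerator and denominator counts
match.  Self-matches are excluded (per-template denominator
N−m·tau−1).  fSampEn = −ln(phi^(m+1)/phi^m).

Numerical and degenerate-input policy:

* a constant series has r = 0; both entropies return value 0 with a
  `degenerate` flag instead of raising, so voxel-wise maps never abort;
* if no (m+1)-length pair retains any similarity (phi^(m+1) = 0),
  fSampEn is undefined: NaN with the flag and a RuntimeWarning, never a
  divide/log error;
* series are **not** z-normalised before entropy: r ∝ SD already makes
  both estimators affine-invariant, and normalising would be redundant;
* the `auto_width` flag (automatic fuzzy-width adjustment) is exposed
  for completeness but not implemented; enabling it raises.  Its exact
  operational definition is not fixed enough to reproduce, and all
  shipped results use the fixed mirrored-quadratic kernel.

The vectorized kernels are checked against a literal O(N²) double-loop
transcription of the defining sums (tests/_reference.py) to 1e−10.

## Dispersional Hurst estimator

For window sizes m in the dyadic set {1, 2, 4, ...} (keeping scales
with at least `min_windows` = 4 complete windows; remainder samples
dropped), compute the sample SD of the window means, then fit
log SD(m) against log m by least squares; H = 1 + slope.  For N = 245
this uses scales 1–32.  A two-point variant (window sizes 2 vs 1) is
exposed as `hurst_two_scale` for comparison; the regression form is
the primary estimator because it uses all available aggregation levels
and the two-point formula is its special case.  Scales with zero SD
are dropped; fewer than three usable scales is an error.  The estimate
is reported unclipped and flagged degenerate outside [0,1].
Classification uses a documented tolerance of ±0.01 around 0.5 for
"random"; values outside (0,1) classify as `OUT_OF_RANGE` rather than
raising.

Validation: on exact fractional Gaussian noise at H ∈ {0.3, 0.5, 0.7},
N = 245, the mean estimate over 200 replicates is within 0.1 of the
generating value (measured biases are about −0.005, −0.016 and −0.045;
the mild downward bias at high H is the known finite-N behaviour of
dispersional analysis).

## Preprocessing chain

Fixed order: discard → motion regression → band-pass → mask → metrics.

* *Discard*: drop the first `n_discard` = 5 volumes (scanner
  equilibration), 250 → 245.
* *Motion regression*: per-voxel OLS on [intercept, 6 motion
  parameters]; residuals are returned with the voxel's temporal mean
  re-added, so intensity masking stays meaningful (the tolerance r is
  SD-based and unaffected).  Collinear design columns are dropped with
  a warning.
* *Band-pass*: zero-phase second-order Butterworth (forward–backward,
  effective 4th-order magnitude) at 0.008–0.1 Hz.  The realized
  response is pinned by tests: a 0.05 Hz sinusoid keeps ≥ 95% of its
  amplitude, a 0.2 Hz sinusoid keeps ≤ 10%.
* *Mask*: voxels whose temporal-mean intensity exceeds 10% of the
  maximum temporal-mean intensity.  The mask is computed on the
  post-discard, motion-regressed but **unfiltered** data, because
  band-passed series are zero-mean and an intensity threshold after
  filtering would be meaningless.
* *Maps*: out-of-mask voxels carry sentinel 0; validity is always the
  mask, never the sentinel.  Degenerate voxels are counted, reported,
  and excluded from whole-brain means.

## Group statistics

* Pearson r with Fisher CI tanh(atanh r ± z_c/sqrt(n−3)); z_c is the
  exact normal quantile 1.959964 (1.96 reproduces the same printed
  bounds).  p from t = r·sqrt((n−2)/(1−r²)) on n−2 df, two-tailed.
* Fisher r-to-z for comparing two independent correlations, two-tailed
  normal p.
* Correlation matrices: all 21 unordered pairs among age, FIQ, VIQ,
  PIQ, H, fApEn, fSampEn, computed within each group; BH-FDR at
  q = 0.05 is applied within each group's 21 tests separately.
* Group t-tests: Student pooled-variance (df = n1+n2−2), the default
  reading of "independent t-test" in common statistics software.
* Moderation: OLS of PIQ on [1, group, entropy_c, group×entropy_c]
  with the entropy centred on the full-sample mean and group coded
  ASD = 1, Control = 2 (kept literally — the printed coefficient
  structure depends on this coding).  Standardised betas are computed
  post hoc as B·SD(x)/SD(y).  The implied per-group slopes
  B_ent + code·B_int are reported to make the coding transparent.
  Under this coding the interaction coefficient equals the Control
  slope minus the ASD slope.
* Missing data fail loudly at table construction; there is no silent
  pairwise deletion.

## Synthetic data

The generators are pure functions of (spec, seed).

* *fGn*: circulant embedding (Davies–Harte) of the exact fGn
  autocovariance gamma(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2;
  a non-nonnegative-definite embedding falls back to spectral
  synthesis with a warning.  Used as the oracle for H recovery
  (lag-one autocorrelation 2^{2H−1}−1 is verified in tests).
* *MIX(p)*: sqrt(2)·sin(2πj/12) with each sample independently
  replaced, with probability p, by uniform noise on [−sqrt3, sqrt3];
  unit marginal variance at every p.  Used as the irregularity
  ordering oracle for the entropies.
* *Phantom*: default 16×16×8 grid × 250 volumes at TR = 2 s — a
  reduced version of a 64×64×37 whole-brain EPI acquisition, chosen so
  the full synthetic pipeline runs in well under a minute per map on a
  single CPU; study-scale geometry is a configuration choice.  Regions
  carry independent per-voxel draws from a chosen generator plus a
  mean intensity; background is near zero; motion traces are smooth
  low-amplitude random walks independent of the signal (only the
  regression contract is under test, not motion–signal coupling).
* *Cohort*: per group, a 7-variate normal with prescribed means/SDs
  (defaults on the scale of a study-like ASD/Control sample) and a
  correlation structure in which the three complexity summaries are
  mutually correlated at 0.99 (a shared latent complexity factor),
  each entropy hits its target correlation with PIQ (defaults −0.702 /
  −0.676 in ASD and 0.197 / 0.201 in Control), and H–PIQ sits at the
  mean of the two entropy targets to keep the matrix positive
  definite.  Infeasible structures raise naming the offending pair.
  Realism deliberately stops at first/second moments and pairwise
  correlations — no IQ discreteness or measurement-error model — which
  is sufficient for exercising the inference code but means passing
  tests say nothing about distributional quirks of real phenotypes.

What the phantom does **not** emulate: haemodynamic response shape,
physiological noise spectra, spatial autocorrelation, motion–signal
coupling.  Passing the end-to-end tests therefore demonstrates the
correctness of the estimators and plumbing, not performance on real
acquisitions.

## Problem sizes used in validation

Series length 245 throughout (the study-like value); 200 replicates
for Hurst recovery; 100 seeds for entropy monotonicity across MIX
levels; 50 length-64 series for the naive-oracle equivalence; 200
replicate n = 200/200 cohorts for moderation-coefficient recovery;
the default 16×16×8×250 phantom for the end-to-end run.  These sizes
give Monte-Carlo error comfortably below the tolerances they are
checked against.

## Known limitations

* The dispersional estimator is mildly biased downward for H > 0.6 at
  N = 245; the bias is measured, within tolerance, and inherent to the
  method at this length.
* fSampEn can be undefined (NaN, flagged) on short or highly regular
  series when no (m+1)-template pair retains similarity.
* The Fisher r-to-z comparison assumes independent groups and
  approximate bivariate normality; n−3 must be positive, so groups
  need at least 4 subjects.
* Group-level numbers that depend on the original participant data
  (group means, full correlation tables, regression coefficients)
  cannot be reproduced from synthetic cohorts; only the
  correlation-table machinery (CI bounds, z, p from printed r and n)
  and the estimator properties are reproduced exactly.
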