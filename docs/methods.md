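# Methods

## Model and assumptions

The myometrial contractile state is reduced to two interacting quantities:
PR-B transcriptional activity and tissue-level inflammatory load.  Each
grows logistically toward a critical (saturating) level and depletes the
other through a mass-action term — PR-B suppresses inflammation
(anti-inflammatory progesterone action) and inflammation suppresses
effective PR-B activity (PR-A-mediated trans-repression is folded into this
term rather than modeled as a third state variable).  Nondimensionalization
by the critical levels and the PR-B depletion rate leaves three parameters:
b (PR-B growth), i (inflammation growth) and k (PR-B anti-inflammatory
strength), all confined to the unit interval because they are assigned from
min–max-normalized expression.

The phase space is the closed unit square.  Its corners (1,0) and (0,1) —
maximal PR-B with no inflammation, and the converse — are the quiescent and
laboring equilibria; both are sinks for interior parameters.  An interior
saddle exists for i < k at ( i(1−b)/(k−ib), b(k−i)/(k−ib) ); its stable
manifold separates the two basins.  Three parameter degeneracies move this
saddle onto a corner: onto the quiescent corner when i reaches k or 1 (or b
or k vanish), destabilizing quiescence (pro-labor); onto the laboring
corner when b = 1 or i = 0 (pro-pregnancy); and onto the origin when
b = i = 0.  At k = b·i the interior-equilibrium expression is singular.

A note on the interior equilibrium's two substitution-order algebraic
forms: they coincide exactly only at k = 1 (or i = 0); the package uses the
form i(1−b)/(k−ib), b(k−i)/(k−ib) everywhere and checks the second form
against it at k = 1 as an algebra guard.

## Probability of labor

The probability of labor at (b, i, k) is the area of the laboring basin
under a uniform measure on initial states — uniform because no empirical
distribution of (B, I) over gestation is available; non-uniform priors are
out of scope.  Two estimators are implemented:

- **Grid (reference).**  One trajectory per cell center of an odd
  resolution×resolution grid (default 201, so the diagonal is sampled
  symmetrically and the invariant axes are avoided), integrated with
  adaptive RK45 (rtol 1e-8, atol 1e-10) in windows of 25 time units,
  stopping when within 1e-3 (Euclidean) of the quiescent or laboring
  corner.  The default horizon is 500 time units because convergence is
  algebraic, not exponential, near the degenerate i = k collision.  States
  are clipped to the square after each window; the domain is forward
  invariant analytically, so clipping only removes floating-point
  excursions.
- **Separatrix (cross-check).**  The saddle's stable manifold is traced by
  backward integration from ±1e-7 along the stable eigenvector; together
  with the boundary arc through the laboring corner it bounds a polygon
  whose shoelace area is the probability.  Grid and separatrix agree within
  max(0.01, 2/resolution) wherever the saddle is interior.

Analytic limit cases bypass integration: i ≥ k or b = 0 give probability 1,
b = 1 with i < 1 gives 0.  Equality tests use absolute tolerance 1e-9
because normalization produces exact 0/1 parameter values by construction.

Three numerical edge cases deserve mention:

- **Degenerate rest continua.**  At i = 0 every point of the I-axis is an
  equilibrium, and at the b = i = 1 corner so is every point of the line
  B + I = 1.  Orbits can converge to these non-corner rest points; they are
  detected by a vanishing velocity (speed < 1e-9 away from both corners)
  and assigned to the nearest attractor, which is where an infinitesimal
  perturbation of the degeneracy would deliver them.  This matters in
  practice: the stratum-minimum sample of every cohort has i = 0 exactly.
- **The b = i = 1 corner.**  The pro-labor (i = 1 ⟹ p = 1) and
  pro-pregnancy (b = 1 ⟹ p = 0) limits contradict each other there, so no
  shortcut applies; the grid method resolves the corner numerically to
  ≈ 0.5, the two collisions balancing across the diagonal.
- **Slow passages.**  Orbits still moving at the horizon are assigned by
  their net drift toward (0,1) versus (1,0) over the last window and
  counted as unresolved; more than 1 % unresolved raises an error advising
  a longer horizon, and the probability table builder retries with a 4×
  horizon in that case.

Probabilities are cached on (b, i, k, resolution, t_max, tol) rounded to 12
decimals; an 18-sample cohort needs at most 108 distinct evaluations.

## Expression handling

Normalization is min–max per gene *within each platform cohort* (pooled
min–max is available as an option; the within-platform choice follows the
two-platform design, which otherwise has no batch correction).  Ties at the
stratum extremes map to exactly 0/1.  Gene aliases (FOXO1/FOXO1A, IL-1β,
CXCL8, …) are resolved by a fixed table.  A predictor assigns b from its
PR-B surrogate and i from its inflammatory surrogate with k = 1 — the
convention that makes quiescence reachable for every i < 1 — and implied
critical levels B_c = I_c = 1.

## Classifier construction and the sweep

For each train/test partition (ceil(n/2) of each group trains; 5 IL + 4 NIL
of the 18-sample cohort), a classifier is a pair of nonparametric 95 %
confidence intervals about the group medians of the classifier score —
labor probabilities for model classifiers, normalized expression for
single-gene nulls, and per-group rectangles (products of two genes'
intervals) for two-gene nulls.  The default interval is the percentile
bootstrap of the median (B = 10,000, seeded); a (min, max) range interval
is available.  At the cohort's group sizes (4–5 training values) the
bootstrap-median percentile interval almost always coincides with the
range interval, because the resample median lands on the sample extremes
with probability above 2.5 %; the two methods therefore give practically
identical sweeps here.  Construction succeeds only when the closed regions
are disjoint (shared endpoints count as overlap).  Test scores in neither
region are no-calls, including scores outside both intervals' span.
Precision with zero classified samples is defined as 0 (keeping averages
well defined, flagged by recall 0); average F-scores aggregate over
constructed classifiers only, while CSR reports the construction rate
separately.

The sweep evaluates all 21 configurations × all partitions (370,440
outcomes for the 18-sample cohort) with the partition axis vectorized.
Bootstrap seeds derive from SHA-256 of (master seed, score kind, group,
training-subset ids), so results are independent of evaluation order,
identical across partitions sharing a training subset, and bit-reproducible
under a fixed master seed; two-gene nulls reuse the per-gene intervals
(same scores, same seeds).  A seeded `subsample` option evaluates a random
subset of partitions for larger synthetic cohorts, with CSR then relative
to the subsample.  Model scores default to a 101-cell basin grid:
probabilities enter the classifiers only through interval comparisons, so
sub-0.01 area precision buys nothing there; the 201-cell grid remains the
reference for reported probabilities.

## Synthetic cohorts

The generator emulates the pooled two-study design: a microarray-like
platform (3 NIL, 3 term-IL, 3 preterm-IL, with the first term-IL sample
dropped to mirror the exclusion of one ambiguous laboring sample) and an
RNA-seq-like platform (5 NIL, 5 IL), totalling 18 samples (10 IL, 8 NIL).
Raw expression is an affine platform transform of a dimensionless group
signal plus Gaussian noise: offset + scale·μ_g(group) + N(0, noise_sd·scale).
Defaults: inflammatory surrogates at μ_NIL = 0.25, μ_IL = 0.75 and PR-B
surrogates mirrored, noise_sd = 0.1 — a between-group separation of five
noise standard deviations, a strong but plausible bulk-transcriptome marker
effect chosen so the normalized values track the noise-free signal at
r ≥ 0.9.  An `effect_size` multiplier scales the separation and `null_mode`
removes it.  `generate_parameter_truth` returns the noise-free normalized
signal for parameter-recovery tests.

What the generator does *not* emulate: count-based RNA-seq noise (negative
binomial), probe effects, within-group biological substructure, or
correlated genes.  Min–max normalization makes the pipeline invariant to
the affine platform factors, which is exactly the property the two-platform
design exercises; passing tests on these cohorts therefore demonstrate the
pipeline's contracts and calibration, not performance on real transcriptome
data.

## Calibration behavior and a known ceiling

On strong-effect cohorts every model predictor constructs on essentially
every partition (CSR 1.0) and in null mode construction collapses (CSR
≤ 0.05 across all 21 configurations).  Average F-scores, however, plateau
near 0.85–0.88 at *any* effect size: with 4–5 training values the
nonparametric interval is in effect the sample range, whose expected
coverage of a fresh same-group score is (n−1)/(n+1) ≈ 0.60–0.67 for
continuous scores (higher when probabilities saturate at 0/1), and the
no-call rule converts every non-covered test sample into lost recall.
Precision stays at 1.0; recall ≈ 0.79 caps F near 0.88.  This is a
structural property of small-sample interval classifiers with abstention,
not a defect of the probability model.

## Problem sizes

Defaults were chosen at analysis scale: 201-cell grids for reported
probabilities (≈1 s per parameter point), 101-cell grids inside the sweep,
and the full 17,640-partition sweep (≈15 s on one core for an 18-sample
cohort).  Calibration checks subsample 500 partitions.

## Limitations

- Parameters are static per patient; gestational time courses (b, i drifting
  over weeks) are not modeled.
- PR-A appears only implicitly through k and i.
- The dimensional rate constants are placeholders — only their dimensionless
  ratios are identifiable from normalized expression.
- The uniform initial-state measure is an agnostic default, not a
  physiological prior.
- Real-data reproduction of the published classifier tables requires the
  original transcriptome matrices, which ship with neither this package nor
  the publications' text.
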