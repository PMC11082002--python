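# Methods

This note documents the models, numerical choices and design decisions
behind `sedshift`, and what the synthetic-data tests do and do not
demonstrate about real sediment-DNA records.

## Data model and preprocessing

A record is a taxon-by-sample count table (samples stratigraphically
ordered) with one calibrated calendar age per sample.  Ages must ascend
strictly with stratigraphic order; tables whose sample order disagrees with
their ages are re-sorted with a warning, and tied ages are rejected.  Each
sub-sample carries a single age (the midpoint of its depth interval);
interval-to-age interpolation is assumed done upstream by the age–depth
model.

Rarefaction draws without replacement (multivariate hypergeometric) to the
minimum sample total by default.  Sampling without replacement is the
variance-correct reading of "rarefied to minimum reads"; a seeded generator
makes it reproducible.  Taxonomy strings use the rank-prefixed,
semicolon-delimited dialect (`k__;p__;c__;…`); collapsing at a rank sums
counts exactly and pools taxa lacking that rank into a reserved
`unclassified` taxon, so per-sample totals are conserved.

Relative abundance is computed two ways, and the distinction matters:

* **Closed** (rows re-normalized to sum 1 over a selected taxon set) — used
  for ordination and diversity, where compositional distances are the
  object of interest.
* **Relative to the full sample total** (rows sum to < 1 over the modeled
  subset) — used for gLV inference.  If the modeled taxa were re-closed,
  the regression intercept would be exactly collinear with
  `Σ_j N_j = 1` and `(r_i, a_ij)` would only be identified up to a row
  shift.  Keeping abundances relative to total reads (the convention for
  "relative abundance of a group" in amplicon studies) breaks the closure
  because the modeled classes cover only part of the community.

Taxon selection keeps taxa with mean relative abundance ≥ 1%, capped at the
most abundant 12 for ordination and 4 for gLV modeling (see below).

## Alpha diversity and state tests

Richness is observed taxa on rarefied counts; Shannon is `−Σ p ln p` in
nats; "Simpson" is the Gini–Simpson index `1 − Σ p²` (bounded in [0, 1];
an inverse-Simpson switch exists).  Between-state differences use the
Kruskal–Wallis test on midranks with tie correction and a chi-square
approximation; with two states this is equivalent to a Wilcoxon test up to
tie handling.

## Ordination, zonation and the state axis

Bray–Curtis dissimilarity `d = 1 − 2 Σ min(x,y) / Σ(x+y)` feeds three
analyses:

* **NMDS** (non-metric MDS, k = 2, 20 seeded random restarts, Kruskal
  stress-1).  The sign of an NMDS axis is arbitrary, so NMDS1 is flipped to
  correlate non-negatively with sample age; NMDS1 then serves as the
  community state variable.
* **ANOSIM and PERMANOVA** with 999 permutations and the (b+1)/(m+1)
  p-value estimator (so p can never be 0; the minimal attainable p at 999
  permutations is 0.001).  ANOSIM follows Clarke:
  `R = (r̄_between − r̄_within) / (n(n−1)/4)` on midranks of all pairwise
  dissimilarities, giving R = 1 under complete separation and R ≈ 0 for
  arbitrary labels.  Both tests run an explicit permutation loop with a
  seeded generator.  Note that with small balanced groups a permutation can
  recreate the observed partition and tie the maximal statistic, so p =
  0.001 is attained only when the group split is large or unbalanced enough
  that recreations are negligible.
* **Stratigraphically constrained zonation** (CONISS-style): agglomerative
  merging restricted to adjacent clusters, with within-cluster dispersion
  `Σ_{i<j∈C} d²_ij / |C|` computed from squared Bray–Curtis
  dissimilarities (the classical method uses Euclidean sums of squares; the
  dissimilarity-based form is used because the distances of interest are
  Bray–Curtis).  The two-state labeling is **not** read off the greedy
  merge tree: a greedy agglomeration's final merge need not be the optimal
  binary split, so the two-state cut is found exhaustively over all n − 1
  contiguous cut points (O(n²) with prefix sums), guaranteeing the
  minimal-dispersion contiguous split.  The greedy tree is still built for
  dendrogram display.

Bimodality of the state axis is assessed with a Gaussian KDE (Silverman
bandwidth by default, absolute-bandwidth override) on a 512-point grid
spanning the data range ± 3 bandwidths; modes are strict interior local
maxima of the gridded density.  Zero-variance input returns a degenerate
single-mode flag.

## Breakpoints, early-warning signals, forecast deviation

**Breakpoints.**  Structural change in an alpha-diversity series is modeled
as piecewise-constant means.  For each candidate break count m ≤ max_m the
segmentation minimizing total residual sum of squares is found by exact
dynamic programming with a minimum segment length; m is chosen by
`BIC = n ln(RSS/n) + (2m + 1) ln n` (each break adds a position and a mean
parameter; RSS is floored at 1e−12 so noiseless series behave).  The
piecewise-constant model is the minimal faithful reading of
"segment-wise regression"; it is also what the exhaustive oracle verifies.

**Early-warning signals.**  Right-aligned sliding windows (default 5
samples, matching a short paleo-record) yield per-window sample variance
(denominator n − 1) and lag-1 autocorrelation (Pearson correlation of the
window with its one-step shift; zero-variance windows are flagged
degenerate with AC recorded as 0).  Right alignment means each value is
attributed to the window's last sample, so rising signals *lead up to* the
transition.  Trend significance uses Kendall's tau against time over the
declared pre-transition range, with the normal approximation — a
conventional choice where no specific test is mandated.  No detrending is
applied by default.

**Forecast deviation.**  An ARIMA(p, d, q) model — default (1, 1, 0) — is
fitted to the state-1 NMDS1 series by maximum likelihood (statsmodels);
h-step forecasts with normal-theory prediction intervals are compared with
the observed state-2 series, and the deviation verdict is
`fraction outside the 95% band > 5%`.  A non-stationary AR estimate is
flagged but returned.  A drift term (`trend='t'`) must be requested
explicitly for a differenced model to extrapolate a ramp; the default
matches R's `arima()`, which drops the mean for d ≥ 1.

## gLV inference and stability

Each stage window (length w = 10 samples, step s = 5; 35 samples give 7
stages, the 7th truncated to 5) yields w − 1 forward-difference equations
per taxon.  Zeros are replaced, before the log only, by half the smallest
nonzero abundance in the window (config-overridable).  Δt comes from the
calibrated ages and varies between sample pairs, so rates are per calendar
year.

**Identifiability bounds the modeled taxon set.**  The ridge solution for
each taxon's coefficient row lies in the span of the window's equations, so
an S × S interaction matrix estimated from w − 1 equations has rank at most
w − 1: with w = 10 a 12-taxon matrix is structurally singular and has no
equilibrium.  The pipeline therefore models the 4 most abundant classes by
default (config `max_taxa_glv`), and `stage_analysis` additionally caps
each window's taxon set at `len(window) − 2` and drops taxa whose mean
abundance in the window is below 0.5% (an effectively absent taxon carries
no dynamical information and only degrades the conditioning of A).
Truncated trailing windows reduce the fold count to the number of
equations available rather than failing.

**Ridge and cross-validation.**  The penalty `λ ‖(a_i1…a_iS)‖²` leaves the
intercept r_i unpenalized.  λ is drawn from 25 log-spaced values in
[1e−4, 1e2] and chosen to minimize mean out-of-fold squared error over
k = 5 contiguous blocks of equations (contiguous folds respect serial
dependence and make the fit fully deterministic).  One λ is shared by all
taxa in a stage by default: per-taxon λ shrinks different rows of A by very
different factors, which routinely makes A numerically singular; a shared λ
keeps the rows on a common shrinkage scale, and the stage Jacobian
`−diag(A⁻¹r)A` is in fact invariant under a uniform rescaling of the
interaction coefficients.  A per-taxon mode is retained for comparison.

**Stability and interactions.**  The interior equilibrium solves
`A N* = r` (rejected when cond(A) > 1e8, with the condition number
reported); analysis proceeds even when some `N*_i ≤ 0`, with a feasibility
flag, since fitted stages near a transition are exactly the ones whose
nominal equilibria go infeasible.  The Jacobian at any state is
`J_ik = δ_ik (r_i − Σ_j a_ij N_j) − N_i a_ik`, which reduces to
`−diag(N*) A` at an interior equilibrium (tested against finite
differences and the algebraic identity).  The stage verdict is stable iff
every eigenvalue real part is negative; the plain mean of the real parts is
the graded "centroid" stability level.  Interaction typing uses growth
effects `e_ij = −a_ij` (positive = activation), so "+/+" means mutual
promotion — with the raw inhibition coefficients the labels would be
inverted, and a `classify_on="raw"` switch exposes that reading.  Pairs
with an exactly zero effect are flagged null and excluded from the type
proportions; per-type strength is the mean |e| over the type's entries
(signed means are ambiguous when effects straddle zero).

## Synthetic data

`simulate_glv` integrates the gLV system with fixed-step RK4 plus optional
multiplicative log-normal environmental noise applied after each step,
scaled by √dt so the noise level is a per-√year diffusion independent of
the integration step; abundances are floored (1e−12 by default) and any
abundance above 1e6 aborts with the blow-up time.

**Two-regime scenario** (the study-shaped fixture): 35 samples spanning
1200–2010 CE, 12 modeled classes plus an `unclassified` remainder
(~20–30% of reads), 20,000 reads per sample drawn multinomially,
environmental noise 0.05 /√yr (≈ 7% between-sample compositional noise).
Two strongly competing core taxa form a bistable pair; a slow linear driver
erodes the resident's growth rate from 0.30 to −0.30 yr⁻¹ across the
record, so the competitor's invasion eigenvalue
`g = r_B − a_BA N_A*` crosses zero (~1320 CE) and the community
reorganizes abruptly, with the deterministic core crossover near 1460 CE.
Background taxa couple to the two core competitors with opposite signs, so
the whole composition differs between regimes without any background taxon
going extinct.  The driver acts on growth rates, not on A, keeping the
interaction matrix identifiable per stage.  Ground truth (parameters,
threshold time, crossover time, per-sample regime labels) is stored in a
JSON sidecar.  The "transition episode" is the interval from stability
loss to crossover; a stage contains the transition when its window overlaps
that episode.

**Fold-approach series** for early-warning validation: a single-taxon gLV
whose growth rate ramps linearly toward zero, so the equilibrium's
eigenvalue −r(t) decays toward the bifurcation; 300 samples at Δt = 0.5
with noise 0.15 give a long pre-transition record on which variance and
lag-1 AC trends are tested (window 25).  The 35-sample scenario is too
short for individually significant EWS trends — a realistic property of
short cores, and the reason EWS power is validated on this longer fixture.

**Recovery fixture** for interaction inference: 3-taxon stable interior
systems observed as 10 replicate 6-sample relaxation episodes (60 samples
total, multinomial counts at 50,000 reads, process noise 0.01).  Replicate
episodes, pooled with `glv.pool_designs`, are essential rather than
cosmetic: a single long series yields collinear regressors (one smooth
transient spans a low-dimensional manifold), and perturbing *within* a
series corrupts every forward difference that straddles a perturbation —
the state jump enters the response as a 1/Δt outlier.  With episodes, no
equation spans a perturbation, each episode contributes an independent
excitation direction, and the ridge fit recovers A with element-wise
correlation > 0.9 and ≈ 98% sign agreement across 50 seeds.  This mirrors
the replicate-perturbation designs used for gLV inference in host-microbiome
studies.

## What the synthetic tests do and do not show

The generator emulates the *shape* of a dated amplicon record: counts are
multinomial at realistic depth, regimes are compositional, the transition
is driver-induced with a genuine loss of local stability.  It does not
emulate DNA degradation or taphonomic smoothing, age-model uncertainty,
primer or extraction bias, OTU-level noise below the class level, or
time-varying interaction coefficients.  Passing tests therefore demonstrate
that the estimators are correct and powered under the stated noise model —
not that a 35-sample core from a real lake will yield significant EWS
trends or a well-conditioned interaction matrix.

## Determinism and provenance

A single master seed is split (via `numpy.random.SeedSequence`) into
per-module seeds for rarefaction, NMDS restarts, each permutation test and
simulation; reruns with the same seed are byte-identical (floats are
written with `%.17g` and parsed with round-trip precision).  Every output
TSV carries a commented header with the package version, command, seed and
timestamp.

## Problem sizes used in validation

Unit and end-to-end tests run at the record's native scale (35 samples);
statistical checks use 50–100 seeded replicates for scenario-level
properties, 1,000 labelings for the ANOSIM null mean, and series of
300–5,000 points for EWS calibration — sizes at which the Monte-Carlo error
of each check is comfortably below its assertion margin.
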