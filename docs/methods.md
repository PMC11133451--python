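# Methods

`wingmod` implements a two-pronged framework for asking whether the
*evolutionary integration* of skeletal proportions — the tendency of the
relative sizes of bones to covary across species — is reorganised along a
continuous covariate, here log10 body mass, across a clade of birds.

## Model and assumptions

The data are a rooted, branch-length-calibrated phylogeny and a species ×
trait table of log10 centroid sizes for 13 skeletal elements (cranium,
mandible; scapula, coracoid, sternum, synsacrum; humerus, ulna, radius,
carpometacarpus; femur, tibiotarsus, tarsometatarsus) grouped into the four
canonical modules head / trunk / wing / leg, plus log10 body mass in grams.

Statistical non-independence of species is modelled through the Brownian
variance–covariance matrix `C` (shared root-to-MRCA path lengths). Pagel's
λ rescales the off-diagonal of `C` and is constrained to [0, 1]: although
`corPagel` permits values outside this range, clamping keeps the covariance
positive semi-definite and matches the biological reading of λ as an
interpolation between independence and Brownian motion. All inverses and
inverse square roots of `C` use a symmetric eigendecomposition with an
eigenvalue floor of 1e-12, which is robust on near-ultrametric trees;
duplicated tips or zero-length pendant edges are reported as singular rather
than silently regularised. Multifurcations are accepted as hard polytomies.

**Phylogenetic signal.** Blomberg's K is the ratio of the observed
MSE0/MSE partition of trait variance to its Brownian expectation,
`K = [MSE0/MSE] / [(tr C − n/(1'C⁻¹1))/(n−1)]`, using the GLS
(phylogenetic) mean in MSE0 — the standard published formula. Reference
implementations are not always explicit about which mean variant they use;
the GLS variant may shift K in the second decimal on real data. λ is estimated by maximising
the profile multivariate-normal log-likelihood (mean and σ² profiled out)
with a bounded scalar search over [0, 1] plus explicit boundary
evaluations; because the whole interval is searched, no warm start from a
prior signal estimate is needed. Ancestral states are the Brownian
GLS/BLUP predictions `â + c_k' C⁻¹ (y − â1)`; the root equals the GLS mean.
These reproduce `phytools::phylosig` and `phytools::fastAnc` to printed
precision (see `tests/test_r_oracle.py`).

**Allometric correction.** Each element's log size is regressed on log mass
by PGLS with a Pagel-λ error structure, λ optimised per element
independently. Residuals (log10 *rCsize*) are allometry-free relative
sizes. The variance profile is a running inter-quartile range (Q3 − Q1,
linear-interpolation / type-7 quantiles) over a 30-taxon mass-ordered
window, truncated at the boundaries so the profile covers all ranks; mass
ties are broken by species name for a deterministic order. The source
description of the window statistic is ambiguous between "first and fourth
quantiles" and the inter-quartile range; the IQR reading is used.

## Method 1: mass-binned integration profiles

Species are mass-ranked and grouped into 20 overlapping bins of 40 taxa;
consecutive bins step by 9 or 10 ranks so the last bin ends at rank n. The
step composition is fixed deterministically as "10s first, 9s last". Within
each bin, 30 replicates each draw 30 taxa without replacement, prune the
tree, refit the per-element allometry *inside the replicate* (so allometric
slopes may differ across the mass range), and compute permutation effect
sizes for all 78 element pairs.

The integration statistic is phylogenetic two-block PLS: trait blocks are
transformed to `E = C^(−1/2)(Y − 1â')`, whose rows are exchangeable under
Brownian motion, and r-PLS is the correlation of the paired first singular
scores of the cross-block covariance (for univariate blocks, the absolute
correlation). The permutation null shuffles the row assignment of the
transformed second block (RRPP-style) rather than re-transforming per
permutation — exchangeability holds after the transform and this is ~100×
cheaper. `Z = (r_obs − mean r_null)/sd r_null` is computed on the raw
permutation distribution (no Box–Cox normalisation); this is
monotone-equivalent at this scale but can offset effect sizes slightly
relative to geomorph's transformed version.

Per pair, replicate-mean Z is divided by √30 (effect sizes scale with the
root of sample size), truncated below at zero, and averaged over the pairs
within each module (head 1, wing 6, trunk 6, leg 3 pairs) and spanning each
module pair (e.g. wing–trunk, 16 pairs) — normalise, truncate, then average,
in that order. Percentile bootstrap envelopes (B = 1000 resamples of the 30
replicates, 1σ and 2σ levels) re-run the whole normalise/truncate/aggregate
chain per draw. Trends are OLS slopes of per-bin values against the bin's
mean log mass over its 40 taxa (the x-coordinate is not stated by the
source workflow; the bin mean is this package's choice).

## Method 2: dispersion from the major covariance axis

Under a single all-species allometric model, each focal pair of residual
columns defines a bivariate cloud; `D_m` is the signed score of each species
on the minor axis (second principal component) of that cloud — its
deviation from the major axis of covariation, inversely related to
integration strength. The PCA is on centred, unstandardised residuals (both
axes are in log10 size units) and is non-phylogenetic, applied to GLS
residuals, replicating the reference workflow. `D_m` is kept signed for
ribbons and plots; the heteroskedasticity regression squares residuals, so
no absolute value is taken.

Mass-dependent integration appears as heteroskedasticity of `D_m` in log
mass. Because mass is right-skewed, each test runs on a mass-stratified
subsample: the mass range is split into 10 equal intervals and 1–10 species
drawn per non-empty interval (sizes vary across iterations by design). The
test is a one-tailed Breusch–Pagan: OLS of `D_m` on log mass, then the
studentised score statistic (n·R² of squared residuals on log mass, χ² with
1 df, via `statsmodels`), halved toward the tail matching the expected
direction. The auxiliary variable is log mass, not fitted values, because
the hypothesis concerns mass. 100 such p-values from the real data are
compared against 100 from a null in which the mass vector is re-assigned to
species at random each iteration ("flame plots"); no multiple-testing
correction is applied, which is exactly why the paired null is produced.
Residuals are computed once globally and subsetted per resample, but the
major axis (and hence `D_m`) is recomputed within each subsample. The
scalar "exceedance" summary (fraction of real p below the null's 5th
percentile) is reporting plumbing only — separation is judged on the
distributions, never gated on that scalar.

Default pairs mirror the focal hypotheses: humerus–carpometacarpus
(dispersion expected to *decrease* with mass), scapula–sternum and
carpometacarpus–sternum (*increase*), and cranium–mandible as a two-tailed
control run in both directions.

## Synthetic data

The generator produces the study conditions end to end: a forward-simulated
Yule tree rescaled to unit depth (n = 228 by default); log mass as a draw
from `N(0, σ² · pagel(C, λ=0.92))` affinely rescaled to exactly
[1.1, 3.25] log10 g (≈13–1800 g); and element sizes
`a_j + b·log_mass + u_j + e_j` with a shared isometric slope b = 1/3,
staggered intercepts, a Brownian residual component u (SD 0.02 at unit
depth, uniform cross-element correlation 0.1) and a tip-level residual e
(SD 0.05 log10 units) whose 13×13 correlation matrix is block-structured by
module and varies with each species' mass. Mass dependence is placed at the
tip level because a Brownian process with lineage-varying correlation has
no standard closed form; the u component preserves phylogenetic structure.

In the `mass_dependent` scenario the within-wing correlation ramps 0.2→0.8
across the mass range, the within-trunk block ramps down 0.7→0.3 and the
wing–trunk block ramps down 0.55→0.15 — the full qualitative structure the
detectors are meant to recover (wing consolidating, trunk and wing–trunk
dissociating with mass). The declining ramps are the steepest for which the
per-species correlation matrix stays positive semi-definite against the low
within-wing correlation at the small-mass end (the binding constraint is
the coupling between the wing and trunk blocks' ones-directions; minimum
eigenvalue across the ramp ≈ +0.026). Head and leg blocks are constant at
0.6 and 0.4. `null` freezes everything at mid-ramp constants
(wing 0.5, trunk 0.45, wing–trunk 0.3), and `control_head` additionally
raises the head block to 0.7 with no mass dependence anywhere. A
nearest-PSD repair is permitted only up to an eigen-shift of 1e-6; anything
larger is an error, not a silent fix.

What the generator does **not** emulate: clade-specific mass clustering
(e.g. passerine dominance of the small-mass end), allometric slopes that
differ between elements or clades, K > 1 phylogenetic signal (a λ-scaled
Brownian draw cannot exceed the Brownian expectation), measurement error,
and missing data. Passing recovery tests therefore demonstrates that the
detectors recover a mass-structured correlation signal of realistic
magnitude under realistic phylogenetic confounding — not that real avian
data must show the same effect sizes.

## Numerical and design choices

- Seed fan-out: one master seed is hashed (BLAKE2) with a key path
  (stage, bin, replicate, …) into per-task 31-bit seeds, so results are
  bit-reproducible and independent of execution order.
- Quantiles everywhere are linear-interpolation (type-7); envelope levels
  are the normal tail masses 15.865/84.135 and 2.275/97.725.
- Degenerate inputs fail loudly: singular covariance, zero-variance traits
  or blocks, isotropic residual clouds (ambiguous major axis), constant
  mass designs, infeasible bin compositions.
- A replicate whose within-bin PGLS fit fails is redrawn once before the
  error propagates with its bin/replicate context.
- λ optimisation uses a bounded search with tolerance 1e-5 for headline
  signal statistics and 1e-3 inside replicate refits, where the residuals
  are insensitive to λ at that resolution.

## Problem sizes used in checks

The calibration and recovery checks run at sizes chosen to make their
Monte-Carlo bands tight while keeping the suite routine to run: estimator
calibration on 64- and 128-tip trees (100-500 replicates), type-I error
at 500 null simulations with 199 permutations, generator-truth recovery at
the full n = 228 with 10 replicates per bin and 99 permutations over 25
seeds, and flame comparisons at the full 100 iterations. The acceptance
script runs method 1 at its full published settings (30 replicates, 999
permutations, 1000 bootstrap draws).

## Known limitations

- The λ-clamped generator cannot produce K > 1 masses, so the headline
  real-data signal values (K ≈ 1.5) are not reproducible from synthetic
  conditions; the package reports what it computes.
- Effect sizes omit the Box–Cox normalisation used by some reference
  implementations (monotone-equivalent; small numeric offsets expected).
- The flame null permutes mass against traits, which destroys the
  trait–mass linkage but not trait–trait phylogenetic structure; this
  mirrors the reference procedure and motivates the head control pair.
- No support for missing elements, OU/EB models, or >2-block integration.
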