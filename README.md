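# wingmod

Does body size reorganise the *evolutionary modularity* of an animal's
skeleton? `wingmod` is a Python toolkit for detecting body-mass-dependent
changes in the evolutionary integration of skeletal proportions across a
phylogeny, built around the avian case: 13 skeletal element sizes (log10
centroid sizes) grouped into head, wing, trunk and leg modules across ~228
bird species spanning four orders of magnitude of body mass. It is aimed at
comparative morphologists who have a time-calibrated tree, a species ×
element size table and a continuous covariate (here log10 mass in grams),
and who want significance-tested answers rather than eyeballed covariance
plots.

## The two detectors

**Method 1 — mass-binned integration profiles.** Species are mass-ranked
into 20 overlapping bins of 40 taxa. Within each bin, 30 replicates of 30
taxa refit the per-element PGLS allometry (log size ~ log mass with a
Pagel-λ error structure) and compute, for all 78 element pairs, the
phylogenetic two-block PLS effect size

> Z = (r_obs − mean r_null) / sd r_null,

where r is the correlation of the paired first singular scores of the
cross-block covariance of `C^(−1/2)`-transformed residuals and the null
permutes rows of the transformed block. Replicate-mean Z is normalised by
√30, truncated below at zero, averaged within/between modules, wrapped in
1σ/2σ bootstrap envelopes (B = 1000) and summarised by OLS trend slopes
against bin mean log mass.

**Method 2 — dispersion from the major covariance axis.** For a focal pair
of allometry-corrected element sizes, each species gets a signed score D_m
on the minor axis of the bivariate residual cloud (its deviation from the
major axis of covariation; small dispersion = tight integration).
Mass-dependent integration is then heteroskedasticity of D_m in log mass,
tested one-tailed (Breusch–Pagan score test, n·R² form) on 100
Gaussian-mass-stratified subsamples and compared against 100 runs on a
mass-permuted null — the "flame plot" comparison.

A synthetic-data module generates the full study conditions (Yule tree,
high-signal log masses, module-structured residual correlations that ramp
with mass), so every stage is testable offline and the pipeline's ability
to recover a known truth is quantified.

## Worked example

```python
from wingmod import run_all, RunConfig, report
from wingmod.synthetic import generate_scenario

tree, table, truth = generate_scenario("mass_dependent", seed=4, n_species=59)
bundle = run_all(table, tree, RunConfig(master_seed=7, n_bins=3, n_rep=5,
                                        n_perm=99, bootstrap_B=200,
                                        flame_n_iter=20))
print(report(bundle))
```

prints (abridged):

```
# wingmod run summary

## Phylogenetic signal of log10 body mass
- Blomberg's K: 0.358
- Pagel's lambda: 0.891
- Brownian root estimate: 1.846 (~70 g)

## Method 1: module integration trends (slope of Z/sqrt(n) vs log10 mass)
- head: -0.2429
- wing: -0.6072
- trunk: -0.2325
- leg: +0.8332
- wing-trunk: -0.9470
...
```

Read it as: the simulated masses carry strong phylogenetic signal
(λ ≈ 0.89, Brownian root ≈ 70 g); each module line is the OLS slope of
mean within-module integration (Z/√n) on log10 mass across the bins — a
positive wing slope means wing bones evolve more in concert among larger
species. At this deliberately tiny size (59 species, 3 bins, 5 replicates)
the slopes are noisy; at the full design (228 species, 20 bins, 30
replicates — the library defaults) the mass-dependent scenario yields a
positive wing slope and negative trunk and wing–trunk slopes in the large
majority of seeds, and the flame plots separate for humerus–carpometacarpus
while the cranium–mandible control overlaps its null.

The same pipeline is scriptable from a shell:

```sh
wingmod simulate --scenario mass_dependent --seed 7 --out fixtures
wingmod run-all --tree fixtures/mass_dependent_7.nwk \
                --traits fixtures/mass_dependent_7.csv --seed 7 --out results
wingmod report --bundle results
```

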