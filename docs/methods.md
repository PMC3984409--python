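# Methods

## The screening problem

In a two-plant plant–soil feedback (PSF) loop, a microbial taxon can only
participate if it has both an *affinity* — it responds asymmetrically to the
two plants, accumulating under one of them — and an *effect* — it changes the
performance of at least one plant. Whole-community surveys of conditioned
soils face a severe signal-to-noise problem: most taxa do neither, so
community-level tests of plant treatments are weak even when a handful of
taxa drive strong feedback. This package quantifies the two traits per OTU
and screens for taxa extreme in both, using data from replicated
"home-and-away" trials: soil conditioned by ragweed or sunflower over
successive growing rounds is replanted with the same species (home) or the
other (away), and final dry biomass is recorded per pot.

The unit of analysis is one trial (40 pots: 2 training plants × 2 final
plants × 10 replicates) and one microbial group (bacteria or fungi, assayed
as community fingerprints whose peak intensities act as abundances). Trials
are independent replicates; nothing is pooled before the cross-trial tests.

## Index construction

All community matrices are Hellinger-transformed first,
`h_ij = sqrt(x_ij / Σ_j x_ij)`, which removes run-to-run differences in total
fingerprint intensity and makes Euclidean-type analyses appropriate for
abundance data. Bray–Curtis dissimilarities are then computed on the
transformed rows.

**Affinity.** On the 20 home pots only (their communities have seen three
successive rounds of selection by a single plant), a canonical analysis of
principal coordinates (CAP) is run with the plant as the single binary
constraint: principal coordinates of the Bray–Curtis matrix, least-squares
regression of the coordinates on the centered plant indicator,
eigen-analysis of the fitted values. A binary factor yields exactly one
canonical axis; its eigenvalue over total inertia is the *affinity variance
fraction* — the share of community turnover attributable to plant identity.
The axis is oriented so ragweed-trained pots score negative (an exact tie of
group means leaves the axis unflipped). Each OTU's affinity index is its
weighted-average position on the axis, weights its Hellinger abundances, so
the index always lies within the range of the site scores. Negative PCoA
eigenvalues (Bray–Curtis is non-Euclidean) are discarded without
Lingoes/Cailliez correction; total inertia is the sum of retained positive
eigenvalues, with retention threshold 1e-8 relative to the largest. The
weighted averages are not variance-expanded; expansion is a documented
alternative that rescales, but does not reorder, the index.

**Effect.** For each plant, on that plant's 20 home + away pots, dry biomass
is regressed on community composition by projection-to-latent-structures
(partial least squares) regression, first component only. Columns are
centered but not scaled (Hellinger values already share a scale). For one
component the solution is closed-form and algorithm-independent:
`w1 = X'y/‖X'y‖`, `t1 = X w1`, `p1 = X't1/(t1't1)`. The X-loadings `p1` are
the effect index, under the sign convention `cov(t1, y) ≥ 0`: positive
loading = found in pots with larger plants. The fit reports two variance
fractions: the share of community variance reconstructed by the rank-one
model (`‖t1 p1'‖²_F / ‖X‖²_F`) and the share of biomass variance explained
(`corr(t1, y)²`). "Loadings" here means X-loadings rather than weights; for
one component the two differ only by covariance smoothing (see Limitations),
and X-loadings are what the standard PLS implementations label loadings.
OTUs absent from the pots used for an index carry an explicit `NA`, never a
silent zero.

**Screen.** Per trial × group, each plant's effect index is regressed on the
affinity index by ordinary least squares (two-sided t-test on the slope,
significance codes at 0.001/0.01/0.05). An OTU is a *potentially important
PSF candidate* for a plant if it falls in the upper or lower `q` tail
(default 2.5 %) of both the affinity index and that plant's effect index,
using linear-interpolation empirical quantiles over non-missing values with
inclusive thresholds (deterministic under ties). Tails are two-sided on both
indices, so an OTU may appear in both plants' screens; a sign-restricted
variant (requiring, e.g., ragweed-side affinity for the ragweed screen) is a
one-line change but is not the default reading. Per-trial candidate counts
for the two plants are compared across trials with a two-sided paired
t-test. No multiple-testing correction is applied across the 40 per-trial
regressions: each trial is reported as an independent replicate.

**Community-level context.** A three-way permutational MANOVA
(trial × training plant × final plant with all interactions, in that order)
partitions the pooled Gower-centered inner-product matrix into sequential
(Type I) sums of squares via orthogonalized term bases; pseudo-F per term is
tested against the residual by free permutation of observations (the
`(1+count)/(1+n_perm)` estimator, so p is never zero). Sequential SS makes
the printed R² column additive with the residual. Restricted (within-trial)
permutation is available as an option but is not the default. NMDS minimizes
Kruskal stress-1 (isotonic regression of configuration distances on the
dissimilarities, primary tie treatment) with one principal-coordinate-seeded
start plus random restarts; the best configuration is centered and rotated
onto its principal axes.

## The synthetic study generator

The generator is the package's test bed: it emulates the replicated
home-and-away design with planted, recoverable structure. Per trial it draws
a fresh log-normal source pool of baseline OTU intensities (so between-trial
turnover dominates pooled community variance, as in real multi-site soil
data), then per pot log-normal intensities around those baselines. A
minority of OTUs carry affinity: their expected abundance is multiplied by
a fold-change in pots whose training plant matches their side (three real
conditioning rounds collapsed into one multiplier; no generational
dynamics). A minority carry effects: per-plant coefficients γ act on
Hellinger-transformed abundance,

    y = β0(final plant) + Σ_j γ_j(final plant) · h_j + ε,   ε ~ N(0, noise_sd²),

with y clipped at zero. `couple_sign` correlates an OTU's affinity side with
the sign of its effect on its own plant; −1 (the default) makes
high-affinity microbes harm their own plant — the negative-feedback
structure under which the harmed plant's effect-versus-affinity regression
has a positive slope.

Defaults (the study conditions; chosen once, with the reasoning below):

| parameter | default | rationale |
| --- | --- | --- |
| n_trials / n_pots_per_cell | 10 / 10 | the real design: 400 pots total |
| n_otus | 500 | fingerprint-scale richness per group |
| frac_affinity, frac_effect | 0.04 | a minority of taxa carry signal; 20 affinity OTUs fit within the 2×2.5 % tails (~25 of 500), so the screen's capacity is not the binding constraint |
| frac_effect_from_affinity | 0.7 | fraction of effect OTUs drawn from the affinity set; the intersection (the true PSF set, 14 OTUs) must dominate the affinity set because pure-affinity taxa are structurally confounded with it (below) |
| affinity_multiplier | 6 | strong conditioning: affinity variance fractions land at ~11–25 %, the minority-turnover regime |
| effect_scale | 6 g | effect sizes of a few grams against β0 = 15/25 g (ragweed/sunflower), keeping the zero-biomass clip rare while the first latent variable captures >70 % of biomass variance in most fits |
| noise_sd | 0.5 g | pot-level biomass noise well below the planted signal |
| baseline_lognormal_sigma | 1.5 | strong source-pool heterogeneity: trial R² ≈ 0.8 in perMANOVA, dwarfing plant terms |
| pot_lognormal_sigma | 0.6 | within-trial pot-to-pot community noise; without it replicate pots would be identical and the ordination degenerate |

Abundances are continuous intensities, not counts, matching fingerprint peak
heights. Sides of affinity OTUs alternate deterministically, so the two
tails are balanced. Every stochastic quantity derives from a single seed via
per-trial child streams: a trial's data are bit-reproducible and do not
change when other trials are added or removed.

What the generator does *not* emulate: taxonomic identity and phylogeny,
compositional sequencing error, spatial structure within pots, asymmetry
between the two plants' candidate counts (affinity sides and couplings are
symmetric by construction, so the generator reproduces the slope-sign and
recovery structure of negative feedback, not the real study's ragweed excess
of candidates), and any mechanistic population dynamics. Passing recovery
tests therefore demonstrates that the estimators detect the planted
covariance structure at realistic size and noise — not that real communities
satisfy the generator's assumptions.

## Numerical choices and degenerate inputs

- Zero-sum community rows, constant biomass, constant constraints, and
  all-identical paired differences raise validation errors naming the stage;
  they are never silently patched.
- Biomass orthogonal to every OTU column (`‖X'y‖ = 0`) raises a dedicated
  no-covariance error.
- Eigen-solvers operate on symmetrized matrices; CAP's constrained
  eigenvalue is floored at zero against rounding.
- Quantile ties at screen thresholds are included (≤ / ≥), making screens
  deterministic under duplicated index values.
- perMANOVA term bases are orthogonalized twice against preceding terms;
  a term adding no dimension beyond its predecessors is reported as aliased
  by name. Terms containing a constant factor (e.g., `trial` in a
  single-trial run) are dropped as dimensionless rather than treated as
  errors.
- TSV round-trips use 17 significant digits (exact for double precision).

## Problem sizes in tests and scripts

The default test suite and the acceptance script run the full ten-trial,
40-pot, 500-OTU design; recovery metrics average 20 independent studies.
Community statistics on the pooled 400-pot matrix use 999 permutations and
6 NMDS starts in the analysis scripts (20 starts remains the library
default for single calls). Oracle tests use small instances (n ≤ 20) where
dense linear algebra is exact.

## Known limitations

- **The effect index measures association, not causation.** PLS X-loadings
  are approximately the column covariance applied twice to γ
  (`p1 ∝ (X'X)² γ` up to scale); Hellinger closure, shared-total variation
  and especially the training factor correlate columns, so taxa that merely
  co-occur with causal taxa inherit part of their loading. Two practical
  consequences, both visible in the synthetic truth: rank agreement between
  the index and planted γ plateaus around 0.85–0.9 even with hundreds of
  pots and zero noise (weights `w1` recover very slightly better, ~0.91,
  which is why the weights-versus-loadings choice matters little in
  practice), and pure-affinity taxa ride the training-driven biomass signal
  into the effect tails, capping screen precision at roughly the fraction of
  affinity taxa that truly carry effects.
- The affinity variance fraction's denominator excludes variance carried by
  negative PCoA eigenvalues; with strongly non-Euclidean dissimilarities the
  fraction is therefore slightly optimistic.
- Free permutation in perMANOVA tests all terms against a single exchangeable
  null; with the enormous trial effect present, plant-term p-values are
  anti-conservative relative to a within-trial restricted scheme (available
  via the `terms`/strata options but not the default).
- First-component PLSR only: multi-component fits, cross-validated component
  choice, and sparse variants are out of scope.
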