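# Methods

This note documents the models the package implements, the numerical choices
behind them, and what the synthetic-data generator does and does not emulate.

## Pedigrees and relationship matrices

Breeding designs are bipartite sire × dam mating lists.  Three kinds are
supported: *nested* (each dam mated to one sire; sires take a small range of
dams), *partial factorial* (each dam mated to a fixed number of sires, each
sire to a fixed number of dams; a biregular assignment is laid out by walking
consecutive dam blocks), and *split egg lot* (nested, plus a stated number of
dams whose eggs are additionally fertilized by a second sire).  Where the
design leaves freedom (which sires take the extra dam, which dams are split),
assignment is deterministic in label order unless a seed is supplied; family
counts are invariant to this choice.

The numerator relationship matrix **A** (twice the kinship matrix) is built
by the tabular method: founders are taken unrelated and non-inbred, `A[i,i]
= 1 + F_i` with `F_i = A[sire_i, dam_i] / 2`, and `A[i,j] = (A[j, sire_i] +
A[j, dam_i]) / 2` for earlier-born `j`.  O(n²) time, dense storage; study
sizes here are well under a few thousand individuals.  A brute-force
coefficient-of-coancestry recursion serves as an independent test oracle.

## Geometric morphometrics

**Centroid size** is the root summed squared deviation of the landmarks from
their centroid.  (The root-summed-squared *inter-landmark distance* variant
equals it times √k for fixed k and changes no shape variable.)

**GPA.** Partial Procrustes superimposition: configurations are centered,
scaled to unit centroid size, and rotated (proper rotations only) onto the
running consensus; the consensus is the renormalized mean of aligned
configurations, iterated to a 1e-10 RMS displacement tolerance.  The GPA
fixed point is unique only up to a joint rotation, so the final consensus is
rotated to a canonical orientation (principal axes; the 180° ambiguity
resolved by the sign of the third moment along each axis, falling back to
the first landmark).  This makes every downstream score exactly invariant to
how the inputs happened to be digitized — rotations, translations and
positive scalings of input configurations move relative-warp scores by less
than 1e-6 (in practice, machine precision).

**Warps.** The thin-plate-spline bending-energy matrix is the upper-left
k × k block of the inverse of the TPS system [[K, Q], [Q′, 0]] with kernel
U(r) = r² log r² and Q = [1 | x | y] evaluated at the consensus.  Its k − 3
positive-eigenvalue eigenvectors are the principal warps.  Partial-warp
scores stack the x- and y-projections of each specimen's deviation from the
consensus onto the principal warps plus two uniform (affine) scores; the
uniform basis is computed as the orthonormal complement of the non-uniform
subspace within the 2k − 4-dimensional shape tangent space (the
Rohlf-style sweep; the Bookstein shear/dilation construction spans the same
subspace at the consensus, so a single variant is exposed).  Relative warps
are the SVD (principal components) of the partial-warp score matrix, each
axis oriented so its largest-magnitude loading is positive.  With the
weighting exponent α = 0 (the default), relative warps coincide with
principal components of the aligned coordinates; α ≠ 0 re-weights principal
warps by eigenvalue^(−α/2) and is supported but not exercised by the tests.

No secondary projection from the Procrustes hemisphere to a tangent plane is
applied beyond the alignment itself; at intraspecific scale the discrepancy
is second order in the shape variation (empirically ~noise², visible in the
PCA-oracle test at the 1e-5 level for 1% landmark noise) and far below any
biological signal analyzed here.

## Growth and condition

The weight–length model is OLS of log₁₀ W on log₁₀ L, fitted once on the
pooled sample (all strains and periods).  Relative condition is
K_n = W / 10^(a + b log₁₀ L).  By OLS construction the geometric mean of K_n
over the fitting set is exactly 1; K_n is invariant to the weight unit when
the regression is refitted in that unit.  ATU is the partial sum of daily
mean temperatures from fertilization through hatch; negative daily means are
legal but flagged.

## The animal model

For trait vector y, V(θ) = Σ_r σ²_r M_r + σ²_e I where M_r is **A** for the
additive term and Z Z′ for iid grouped terms (dam, family, sire).  The
restricted log-likelihood uses the orthonormal-error-contrast convention

    ℓ = −½ [ (n−p) log 2π + log|V| + log|X′V⁻¹X| − log|X′X| + y′Py ],

whose constants make ℓ directly comparable with an explicit error-contrast
evaluation (the test oracle).  Because ℓ depends on y only through Py, the
optimizer works on OLS residuals scaled to unit variance: fits are then
exactly invariant to trait translation and scale (components scale by c²).

Optimization is bound-constrained L-BFGS-B on log-variances (bounds
[−12, 6] on the unit-variance scale; a component ending below 2e-5 of the
trait variance is reported as exactly 0), with three restarts from spread
variance shares and ties broken by best likelihood.  Standard errors of
h² = V_a/V_p and m² = V_m/V_p come from a delta-method expansion around the
central-difference Hessian of ℓ on the log scale (step 1e-4).

**Likelihood-ratio tests** of one variance component use 2Δℓ against χ²₁, as
commonly reported.  A component null lies on the boundary of its parameter
space, so this reference is conservative (the asymptotic null is the 50:50
mixture of a point mass at 0 and χ²₁; expected rejection at nominal 5% is
2.5%).  The mixture p-value is available via `boundary_correction=True` and
is what the null-calibration tests assert against, since only it is
calibrated at the nominal level.

**Identifiability.** In a nested design without split egg lots the full-sib
family partition coincides with the dam partition and family variance is
confounded with the sire–dam structure; the family term is refused with an
explanatory error in that case.  More broadly, separating dam and family
variance from additive variance with ~30 families is weakly identified:
matched four-component fits show boundary-induced downward bias in V̂_a
(and additive-only fits absorb dam/family variance upward).  Recovery tests
therefore use identifiable worlds per question — additive-only worlds for h²
recovery, an additive+dam world for m² recovery — rather than a single
misspecified compromise.

**Bivariate model.** For two traits on the same individuals,
V = G ⊗ A + R ⊗ I with 2×2 additive (G) and residual (R) covariance
matrices, each parameterized by its Cholesky factor so every proposal is
PSD.  r_g = G₁₂/√(G₁₁G₂₂); the LRT pins G₁₂ = 0.  Traits are standardized
internally; r_g is scale-free.

**Strain comparisons** fit strain (+ maturation where it varies) as fixed
effects with iid sire and dam random effects, compute LS-means with the
maturation covariate balanced at 0.5, and adjust pairwise comparisons by the
Tukey–Kramer studentized range with between-family degrees of freedom
(n_families − n_strains) — a deliberately conservative df choice for a
family-structured design.

## Multivariate statistics

Wilks' Λ = |W|/|W+B| with Rao's F approximation; the homogeneity-of-slopes
MANCOVA compares residual scatter of the separate-slopes multivariate linear
model against the common-slope model.  If a scatter matrix is singular the
scores are truncated to their leading principal axes (logged).  The
leave-one-out DFA uses a pooled-covariance linear discriminant with *equal*
priors (group sizes are design artifacts, not prevalence; SAS's default
proportional priors would differ for unbalanced subsamples), refit without
each observation in turn; the equal-count per-family subsample requires an
explicit seed.  Repeated measures on family means is a split-plot ANOVA
(families whole plots, periods within) computed by sequential projection so
the nesting of family in strain yields correct degrees of freedom; strain is
tested against family-within-strain, period and the interaction against the
residual.  Sphericity is not corrected — with three periods and the
simulated compound-symmetric worlds the tests are calibrated, but strongly
autocorrelated real data would need a correction this package does not
provide.

## Synthetic studies

The generator emulates the experiment's statistical skeleton, with defaults
chosen once as the stated world:

- **Designs**: 12-family nested (12 dams × 5 sires), 30-family partial
  factorial (15 × 10, each sire × 3 dams, each dam × 2 sires), 28-family
  split-egg-lot (20 × 10 with 8 dams split) — 70 families; 8 offspring per
  family by default (the per-family sampling scale of the study); 3 periods.
- **Shape**: each latent trait t has variance components (V_a, V_m, V_c,
  V_e), default (0.5, 0.05, 0.05, 0.4) so h² = 0.5 — the study's median
  heritability scale — with small dam/family components.  Trait values
  displace the 13-landmark template along fixed orthonormal non-affine axes
  (lowest-bending-energy principal warps: large-scale body-depth /
  caudal-peduncle-like deformations) at 0.03 Procrustes units per latent sd,
  a realistic intraspecific shape variance.  Landmark digitization noise is
  0.002 units per coordinate (sub-5% of the biological signal along an
  effect axis, typical of careful digitization), so realized axis
  heritability is within ~1% of the latent value.  An optional per-period
  consensus drift (0.01 units/period along a further warp axis) emulates
  developmental change of the mean shape.
- **Size**: length = strain mean + latent genetic/dam/family/environment
  parts, grown multiplicatively over periods; weight follows
  log₁₀ W = −5 + 3.1 log₁₀ L + N(0, 0.05) — a standard salmonid allometry.
  Maturation is Bernoulli(0.2) at periods 2–3.  Per-family development rate
  (ATU at 9.5 °C incubation) and per-dam egg diameter are included as
  auxiliary phenotypes.
- **Nuisance**: each configuration receives a random rotation, translation
  and scale (80–140 digitizing units) before landmark noise — GPA must undo
  these exactly, and tests assert it does.
- **Reproducibility**: one root seed spawns named child streams (genetics,
  shape, size, nuisance, maturation, development), so adding a stage never
  perturbs earlier draws; fixture trees are byte-identical per seed.

What the generator does **not** emulate: tank/density effects beyond iid
family terms, mortality and tag loss (real periods resample shrinking
families), measurement correlation between length and shape beyond
allometry, non-Gaussian trait distributions, and selection.  A green
recovery test therefore establishes that the estimation chain is unbiased
under the stated Gaussian world — not that the field estimates of any
particular dataset are right.

## Degenerate inputs and tie-breaks

Collinear landmarks make the TPS system singular (error).  Traits with zero
variance are refused by the REML fitter; the strain-comparison wrapper
returns the exact degenerate answer (zero differences, p = 1) instead.
Relative-warp sign indeterminacy is resolved by the largest-loading-positive
rule; eigen-near-ties (isotropic noise) make individual axes ill-defined,
which the invariance tests handle by canonicalizing the GPA frame rather
than by loosening tolerances.
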