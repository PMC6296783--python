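# Methods

This note documents the models implemented in `soilmultifun`, the
defaults of the synthetic-experiment generator, and the numerical
choices made where the design was genuinely open.

## The experimental template

The analyses are organised around a split-plot biodiversity experiment:
six rings (whole plots), three at ambient and three at elevated CO₂;
within rings, plots receive ambient or enriched N; plant species
richness is sown at 1, 4, 9, or 16 species from a pool of 16 grassland
species in four functional groups (C3 grasses, C4 grasses, forbs,
legumes), with 32/32/15/12 replicates per richness level in each of the
four CO₂ × N cells — 91 plots per cell, 364 in total. Monocultures
cover every species in every cell; 4-species mixtures span 1–4
functional groups; 9-species mixtures carry at least three groups;
16-species plots contain the whole pool.

## Diversity indices

All taxonomic indices operate on relative abundances pᵢ and are
scale-invariant, so percent covers and proportions give identical
results. Shannon entropy uses natural logs (configurable base). Three
conventions matter and are implemented explicitly:

- a plot whose sown community went entirely extinct (total cover 0)
  carries **zero** for every diversity and functional-diversity index;
- a surviving monoculture has undefined Pielou evenness (ln 1 = 0) and
  is reported as NaN, excluded from evenness analyses rather than
  forced to 0 or 1;
- Simpson evenness is the inverse-Simpson index divided by realized
  richness — the standard form; the definition is isolated in one
  function and swappable.

## Functional diversity

Gower distance is the mean over traits of |xᵢ − xⱼ|/range(trait),
bounded in [0, 1] and invariant to affine rescaling of any single
trait. The distance matrix is embedded by principal coordinates
analysis; when the doubly centred matrix has negative eigenvalues
beyond 10⁻⁹ of the leading one, the Cailliez constant (default) or the
Lingoes constant is applied and the embedding recomputed, after which
coordinates reproduce the corrected distances to ~1e−8. Axes with
eigenvalue above 10⁻⁹ × the largest are retained.

FDis is the abundance-weighted mean distance to the abundance-weighted
centroid and is defined for every non-empty community (0 for
monocultures). FRic is the plot hull volume divided by the pool hull
volume on the same axes; FEve is Villéger's minimum-spanning-tree
index; FDiv the hull-vertex divergence index. FRic/FEve/FDiv require at
least three functionally distinct species and are NaN otherwise.

Numerical choices: hull-based indices (FRic, FDiv) use a common reduced
axis count m = min(retained axes, minimum qualifying richness − 1) so
every qualifying plot spans a hull, while FEve and FDis use all
retained axes; in one dimension the "hull volume" is the range. MST
ties are broken by species-name lexicographic order, making the tree —
and FEve — deterministic under permutations of the input. Degenerate
hulls (coplanar points) yield NaN rather than an error. Trait values
are pool-level constants: the generator attaches no treatment-specific
trait variation, so analyses of trait plasticity are out of scope.

## Multifunctionality

Functions are min-max standardised once across the analysed plot set
(not per treatment). Average multifunctionality is the plain mean of
the four standardised functions, complete cases only. Threshold counts
use **≥** against t% of each function's maximum *observed raw* value,
t ∈ (0, 100]; counts are non-increasing in t by construction. The
threshold profile regresses the count on ln(sown richness) by OLS
(slope and its standard error per t; a linear-richness regressor is
available). The evenness of functions treats the four standardised
values like species abundances: H = −Σ q ln q with q = std/Σ std, and
evenness H/ln 4; an all-zero standardised vector has evenness 0, the
same convention as the empty community.

## Assay conversions

- Basal respiration: mean of hours 14–24 **inclusive** (11 readings);
  the window is configurable since endpoint conventions differ between
  laboratories.
- MIRR: mean of the three smallest readings within hours 1–10 of a
  glucose-amended run (1-based hour indexing from the start of the
  measurement); invariant to permutations within the window.
- Microbial biomass C = 38 × MIRR (µg C g⁻¹ dry soil for MIRR in
  µl O₂ g⁻¹ h⁻¹); the factor is an exposed constant.
- %WSA = (water-stable − coarse)/(initial − coarse) per duplicate, with
  the 4.0 g initial mass as default; duplicates are averaged **after**
  the per-duplicate fraction so each keeps its own denominator.

## Split-plot Type III ANOVA

The model is response ~ CO₂ + Ring(CO₂) + N + lnPSR + CO₂:N + CO₂:lnPSR
+ N:lnPSR + CO₂:N:lnPSR with sum-to-zero factor coding. Type III SS are
computed as the RSS difference between the full model and the model
with the term's columns removed. CO₂ — a whole-plot factor — is tested
against MS[Ring(CO₂)] with the conventional nested 4 df; all other
terms against the plot-level residual.

Two deliberate choices:

- **Covariate centring.** ln richness is centred before building
  interaction columns. This makes the factor main effects orthogonal to
  the factor × richness interactions in balanced designs (so Type III
  equals sequential SS there) and means their tests refer to the
  average log richness rather than to richness 1.
- **Degrees-of-freedom bookkeeping.** The conventional nested coding
  gives Ring(CO₂) 4 df and a model rank of 12. The table layout used in
  SAS-style reports counts the six-ring block as 6 df, i.e. model
  df = 13 and residual df = n − 14 (301 at n = 315). Both accountings
  are exposed on the result (`model_df`/`residual_df` vs
  `*_caption`); F tests use the conventional residual df.

An optional Satterthwaite mode targets unbalanced designs: the expected
mean-square coefficient of the ring variance component is extracted
from each Type III quadratic form (tr Z′AZ), the CO₂ denominator is
assembled as the matching linear combination of the ring and residual
mean squares, and its df follow the Satterthwaite approximation. In
balanced designs this reduces exactly to the classical MS[Ring(CO₂)]
denominator.

Sensitivity refits (excluding monocultures; replacing sown with
realized richness) reuse the same machinery via `ModelSpec` flags. No
cross-response multiplicity correction is applied; raw p values are
reported per response.

## Recursive path model

Four observed variables — ln richness (exogenous), functional
dispersion, evenness of functions, average multifunctionality — with
the default path set {PSR→FDis, PSR→evenness, FDis→EM, evenness→EM}, no
direct PSR→EM path, and uncorrelated residuals. For such recursive
systems the equation-wise least-squares solution on the sample
covariance matrix is the maximum-likelihood optimum; the implementation
computes it in closed form and (by default) polishes it numerically
against the ML discrepancy F_ML = ln|Σ(θ)| − ln|S| + tr(SΣ⁻¹) − p as a
safeguard. Fit statistics: χ² = (n−1)F_ML against the saturated model,
df = 10 moments − 8 free parameters = 2, AIC = χ² + 2k. Standardized
coefficients are raw × sd(source)/sd(target) on the sample scale.
`compare_paths` refits with one added path and returns the AIC
difference, standing in for modification indices. The sample covariance
must be positive definite (exactly collinear inputs are rejected), and
n must exceed the parameter count.

## Synthetic-experiment generator

The generator is first-class, tested code; its defaults *are* the study
conditions the rest of the package is validated against.

Soil functions follow y = μ + a·ln R + b·[CO₂] + c·[N] + ring + λ·u + ε
with ring effects N(0, σ²_ring) per ring, a standard-normal latent
factor u shared by respiration and microbial biomass C, and residuals
redrawn (never clipped) until the value is positive (and ≤ 1 for the
aggregate fraction), so no point mass accumulates at the boundary.
Defaults (units in the field's conventions):

| function | μ | a (per ln R) | b (CO₂) | c (N) | σ_ring | σ_ε | λ |
|---|---|---|---|---|---|---|---|
| root biomass (g m⁻²) | 300 | 120 | 10 | 15 | 30 | 228 | — |
| respiration (µl O₂ h⁻¹ g⁻¹) | 1.2 | 0.145 | 0.02 | 0.04 | 0.12 | 0.33 | 0.40 |
| microbial C (µg C g⁻¹) | 200 | 42 | 5 | 8 | 10 | 41 | 67.5 |
| WSA (fraction) | 0.55 | 0.009 | 0.002 | 0.004 | 0.07 | 0.056 | — |

These magnitudes were calibrated once, analytically, to the effect
structure the analyses assume: richness explains roughly 21%, 22%, 7%,
and 1% of the variance of the four functions respectively; the latent
loadings put r²(respiration, microbial C) near 0.45 while every other
pair stays below ~0.1; the aggregate fraction carries a large ring
(block) component. With ln R having variance ≈ 1 over the design, these
follow directly from a²·Var(ln R)/σ²_total and λ_r·λ_m in the
covariance.

Covers are symmetric-Dirichlet over the surviving sown species with
concentration α₀ = 2, multiplied by 0.5 under enriched N and 0.8 under
elevated CO₂ — resource addition erodes evenness. Survival is
per-species Bernoulli with logit(p_ext) = −4 + 0.15·R + 0.5·[N], so
extinctions are rare in monocultures and increasingly common in diverse,
fertilised plots (realized < sown richness). The Dirichlet family is an
assumption: the distributional family of real cover data is unknown,
and only the evenness ordering it induces is relied on downstream.

Traits are lognormal around functional-group centroids (within-group
log-sd 0.12), giving strictly positive values and between-group
variance exceeding within-group variance. The glucose-amended
respiration series is a deterministic template (disturbance decay +
logistic growth over 24 h, trough inside the first 10 h) plus Gaussian
noise, built so MIRR extraction is testable against the template.

What the generator does **not** emulate: multi-year community dynamics,
within-plot spatial structure, treatment-dependent trait plasticity,
non-Gaussian measurement error, and any correlation between covers and
soil functions beyond what richness induces. Passing tests therefore
validate the *computations* under a plausible effect structure, not
field-level conclusions about real soils.

## Problem sizes used in the test suite

The statistical checks run at the design's own size: type-I-error
calibration of the richness test uses 1000 replicates of the 364-plot
experiment; path-coefficient recovery uses 500 replicates at n = 364;
index-bound checks use 10⁴ random communities. The whole suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- FRic depends on the retained-axis convention; other conventions
  (fixed axis count, quality-threshold selection) give different
  absolute values, though rankings are stable in practice.
- The ANOVA's Satterthwaite mode approximates; with severe imbalance a
  full mixed-model (REML) analysis would be preferable and is out of
  scope.
- The path model treats all variables as observed and Gaussian;
  measurement error in FDis or evenness attenuates its coefficients.
- Tables are exchanged as CSV only; no plotting is included.
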