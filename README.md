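# soilmultifun

Soil ecosystem **multifunctionality** analysis for factorial biodiversity
experiments, built around the design of a long-running grassland
experiment in which plant species richness (1, 4, 9, or 16 species) is
crossed with ring-level CO₂ enrichment and plot-level nitrogen addition
in a split-plot layout (six rings, 364 plots).

The package is for ecologists who have (or want to simulate) plot-level
species covers, species traits, and several ecosystem functions, and who
want to ask: *does plant diversity sustain many soil functions at once,
and through what community properties?*

## What it computes

Given a plot × function table (root biomass, soil basal respiration,
microbial biomass C, water-stable aggregate fraction), plot × species
covers, and a species × trait matrix:

- **Taxonomic diversity** — realized richness, Shannon diversity
  *H* = −Σ pᵢ ln pᵢ, Pielou evenness *J* = *H*/ln *S*, and Simpson
  evenness (1/Σ pᵢ²)/*S*.
- **Functional diversity** — Gower distances over the traits, PCoA with
  Cailliez/Lingoes correction, then FRic (convex-hull volume fraction),
  FEve (minimum-spanning-tree evenness), FDiv (abundance toward hull
  extremes), and FDis (abundance-weighted dispersion around the
  weighted centroid).
- **Multifunctionality** — the *averaging* approach (mean of the four
  functions min-max standardised to [0, 1]); the *multiple-threshold*
  approach (for each t ∈ 1..99%, the count of functions at or above t%
  of their maximum observed value, and the OLS slope of that count on
  ln richness); and the Shannon evenness of the four standardised
  functions treated like species.
- **Assay conversions** — basal respiration as the mean O₂ consumption
  of hours 14–24; MIRR as the mean of the three lowest hourly readings
  within the first 10 h after glucose amendment; microbial biomass C =
  38 × MIRR; %WSA = (water-stable − coarse)/(4 g − coarse).
- **Inference** — split-plot Type III ANOVA (CO₂ tested against the
  ring-within-CO₂ mean square, everything else against the residual),
  pairwise Pearson correlations, best-performing monocultures per
  function and environment, and a recursive path model in which
  ln richness acts on multifunctionality through functional dispersion
  and the evenness of functions (ML fit to the covariance matrix,
  χ² = (n−1)·F_ML, df = 2, AIC = χ² + 2k).
- **Synthetic experiment** — a generator producing the full design and
  all inputs with the effect structure above (log-linear richness
  effects, ring blocks, a shared latent factor coupling respiration and
  microbial biomass, evenness erosion under resource addition), so the
  whole pipeline is testable without any field data.

## Worked example

```python
import soilmultifun as smf
from soilmultifun.multifun import multifunctionality_table

params = smf.SimulationParams(seed=42)
design = smf.generate_design(params)
functions = smf.generate_soil_functions(design, params)
mf = multifunctionality_table(functions)
print(design[["sown_richness"]].join(mf).groupby("sown_richness")
      ["avg_multifunctionality"].mean().round(3))
```

prints

```
sown_richness
1     0.379
4     0.471
9     0.510
16    0.554
```

Average multifunctionality climbs from 0.379 in monocultures to 0.554
in 16-species mixtures (+46%): higher-diversity plots run all four soil
functions at higher standardised levels simultaneously. The split-plot
ANOVA on the same run gives F ≈ 91 for the ln-richness term on root
biomass (p < 0.001) while CO₂, N, and the interactions stay
non-significant, and the threshold profile of the count-on-richness
slope is humped — 0.05 at t = 10%, 0.47 at t = 50%, 0.04 at t = 90%.
The `examples/` directory has one short script per capability
(simulation, diversity indices, functional diversity,
multifunctionality, assay conversions, ANOVA/correlations, path model).

A thin CLI chains the stages over CSV files:

```bash
soilmf simulate --seed 1 --out run/
soilmf all --seed 1 --out run/        # simulate -> ... -> path model
```

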