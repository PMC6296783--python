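"""Functional-diversity indices from traits and abundances.

Gower distances over five traits -> PCoA embedding (Cailliez-corrected
if needed) -> FRic (hull volume fraction), FEve (minimum-spanning-tree
evenness), FDiv (abundance toward hull extremes), FDis (weighted
dispersion around the weighted centroid).
"""

import soilmultifun as smf

params = smf.SimulationParams(seed=42)
pool = smf.build_species_pool()
traits = smf.generate_traits(pool, params)
design = smf.generate_design(params)
covers = smf.generate_covers(design, params)

space = smf.pcoa_embed(smf.gower_distances(traits))
print(f"retained PCoA axes: {space.coordinates.shape[1]} "
      f"(correction: {space.correction})")

fd = smf.community_fd(covers, traits)
summary = design[["sown_richness"]].join(fd).groupby("sown_richness").mean()
print(summary.round(3).to_string())
# All four indices rise with sown richness. FDis is defined for every
# plot (0 for monocultures); FRic/FEve/FDiv need >= 3 species and are
# NaN below that, so the richness-1 means reflect only the all-extinct
# plots, which carry 0 for every index by convention.
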