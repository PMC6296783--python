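"""Recursive path model: how diversity drives multifunctionality.

Richness (ln scale) acts on average multifunctionality only through two
mediators - the functional dispersion of the plant community and the
evenness of the four functions. The model is fitted to the sample
covariance matrix by maximum likelihood; with 10 moments and 8 free
parameters it has 2 df.
"""

import numpy as np
import pandas as pd

import soilmultifun as smf
from soilmultifun.inference import DEFAULT_PATHS, compare_paths, fit_path_model
from soilmultifun.multifun import function_evenness, standardize_functions

params = smf.SimulationParams(seed=42)
pool = smf.build_species_pool()
design = smf.generate_design(params)
traits = smf.generate_traits(pool, params)
covers = smf.generate_covers(design, params)
functions = smf.generate_soil_functions(design, params)

std = standardize_functions(functions)
data = pd.DataFrame(
    {
        "ln_psr": np.log(design["sown_richness"].astype(float)),
        "fdis": smf.community_fd(covers, traits)["FDis"],
        "evenness_func": function_evenness(std)["evenness_func"],
        "avg_multifunctionality": std.mean(axis=1),
    }
)

fit = fit_path_model(data)
print(f"n = {fit.n}, chi2 = {fit.chi2:.2f}, df = {fit.df}, AIC = {fit.aic:.2f}")
for (src, dst), value in fit.standardized.items():
    print(f"  {src} -> {dst}: standardized coefficient {value:.3f}")
for var, r2 in fit.r2.items():
    print(f"  R^2({var}) = {r2:.3f}")

delta = compare_paths(data, DEFAULT_PATHS, ("ln_psr", "avg_multifunctionality"))
print(f"delta AIC from adding a direct richness -> multifunctionality path: "
      f"{delta:+.2f}")
# A positive delta AIC would mean the direct path is not supported. On
# this synthetic run it is negative: the generator writes the diversity
# effect straight into the soil functions, so the two mediators capture
# it only partly and some direct association remains. On data where
# mediation is complete the same comparison returns about +2.
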