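"""Taxonomic diversity and evenness from plot cover vectors.

Shannon entropy (nats), Pielou evenness, and inverse-Simpson evenness
are all computed from relative covers, so the cover scale (percent vs
proportion) does not matter.
"""

import pandas as pd

import soilmultifun as smf

covers = pd.DataFrame(
    {
        "Poa pratensis": [1.0, 0.5, 0.90, 0.0],
        "Lupinus perennis": [0.0, 0.5, 0.05, 0.0],
        "Achillea millefolium": [0.0, 0.0, 0.05, 0.0],
    },
    index=["monoculture", "even_pair", "dominated", "all_extinct"],
)

table = smf.diversity_table(covers)
print(table.round(4).to_string())
# The even pair reaches the Shannon maximum for two species (H = ln 2,
# evenness 1); dominance pushes evenness down; the monoculture has no
# defined Shannon evenness (NaN) but Simpson evenness 1; a plot whose
# sown community went extinct carries zeros by convention.
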