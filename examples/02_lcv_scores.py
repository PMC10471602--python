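"""Compute Local Coefficients of Variation (LCV) and show what they control for.

LCV ranks each gene's CV among genes of similar mean expression (window of
500 by default; 100 here for the small example), so a gene's score reflects
its variability relative to expression-matched peers, on a 0-100 scale.
Genes with a planted 4x dispersion in the SB-maternal groups score high there
and unremarkably elsewhere.
"""

import canalex as cx

config = cx.SimulationConfig(n_genes=500, seed=42)
counts, meta, truth = cx.simulate_experiment(config)

stats, scores = cx.lcv_pipeline(counts, meta, window_size=100)

planted = truth.genes(var_variant="maternal_SBhigh")
sub = scores.scores.loc[planted, ["PLxPL-200", "PLxSB-200", "SBxPL-200", "SBxSB-200"]]
print(f"median LCV of {len(planted)} genes with 4x dispersion planted in the "
      "SB-maternal groups:")
print(sub.median().round(1).to_string())
print("\nhigh scores in SBxSB and SBxPL, near-median elsewhere: the planted "
      "variability is detected where it was planted, independent of mean level.")
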