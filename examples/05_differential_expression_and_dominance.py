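"""Differential expression, gene-level inheritance calls, and proportion tests.

All six pairwise cross-type contrasts are Wald-tested at one time point
(adjusted P < 0.1); each gene's significance flags and fitted means feed the
inheritance classifier.  Proportion tests then ask whether fewer genes
separate a hybrid from its maternal pure cross than from the other pure
cross, with Bonferroni control across the comparisons.
"""

import canalex as cx

config = cx.SimulationConfig(n_genes=800, seed=42)
counts, meta, truth = cx.simulate_experiment(config)
filtered, removed = cx.filter_low_counts(counts, min_total=10)
print(f"{removed} genes below 10 total reads removed; {filtered.n_genes} tested")

results = cx.pairwise_contrasts(filtered, meta, time_point=200)
for pair, res in sorted(results.items(), key=lambda kv: sorted(kv[0])):
    a, b = res.contrast
    print(f"  {a} vs {b}: {res.n_significant()} DE genes (padj < 0.1)")

calls = cx.calls_to_frame(cx.classify_mean_inheritance(results))
print("\ninheritance patterns of mean expression:")
print(calls["pattern"].value_counts().to_string())

n = filtered.n_genes
for pure in ("PLxPL", "SBxSB"):
    c1 = results[frozenset((pure, "PLxSB"))].n_significant()
    c2 = results[frozenset((pure, "SBxPL"))].n_significant()
    chi2, p = cx.proportion_chi2(c1, n, c2, n)
    exact, rounded = cx.bonferroni_threshold(0.05, 4)
    star = " *" if p < exact else ""
    print(f"\n{pure}: PLxSB contrast {c1} vs SBxPL contrast {c2} DE genes -> "
          f"chi2 {chi2:.3f}, P {p:.3g} (Bonferroni threshold {rounded}){star}")
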