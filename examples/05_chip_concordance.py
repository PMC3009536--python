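"""Test whether phenotype-matched TF binding prefers related modules.

Each module gets a hypergeometric enrichment p for a TF's bound targets;
modules sharing (or related to) the ChIP dataset's phenotype form the
"related" group, and a one-sided Mann-Whitney test asks whether their
enrichment p-values are stochastically smaller than the unrelated group's.
The per-bin log2 ratio of the two p-value distributions shows where the
preference concentrates.
"""

from phenomod import concordance_screen, enrichment_ratio_profile
from phenomod.simulate import simulate_chip_concordance

modules, chips, ontology, universe = simulate_chip_concordance(
    n_related=10, n_unrelated=30, concordance=0.8, seed=0
)

results = concordance_screen(modules, chips, ontology, universe, fdr_alpha=0.05)
r = results[0]
print(f"ChIP phenotype    : {r.chip_phenotype}")
print(f"related modules   : {len(r.related_module_pvalues)}")
print(f"unrelated modules : {len(r.unrelated_module_pvalues)}")
print(f"Mann-Whitney p    : {r.mw_pvalue:.3g}")
print(f"BH-adjusted       : {r.fdr_adjusted:.3g}  significant: {r.significant}")

bins = [0, 0.025, 0.25, 0.5, 0.75, 1.0]
profile = enrichment_ratio_profile(
    r.related_module_pvalues, r.unrelated_module_pvalues, bins
)
print(f"log2 ratio per bin {bins}: {[round(x, 2) for x in profile]}")
print()
print("The strongly positive first-bin ratio says related modules pile up")
print("below p < 0.025 — the TF assayed under this phenotype binds inside")
print("the phenotype's own modules far more than elsewhere.")
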