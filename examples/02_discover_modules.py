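"""Discover phenotype-specific coexpression modules with annealing.

One unweighted coexpression network is thresholded per dataset (top 5% of
gene pairs by Pearson r); the multi-objective simulated annealing search
then looks, per phenotype, for gene sets that are large, dense where they
occur, denser in the phenotype's datasets than elsewhere, and dense
*specifically* in the phenotype's datasets (hypergeometric upper tail).
Candidates are filtered at size >= 7, density >= 0.66, BH-FDR < 0.01.
"""

from phenomod import MOSAConfig, SimulationConfig, simulate_collection
from phenomod.pipeline import discover_modules

bundle = simulate_collection(SimulationConfig(seed=1))
modules, networks, universe = discover_modules(
    bundle.datasets, MOSAConfig(seed=1, restarts=2)
)

print(f"{'module':<10}{'size':>5}{'density':>9}{'diff':>7}{'raw p':>11}{'BH p':>11}")
for m in modules:
    print(
        f"{m.module_id:<10}{m.size:>5}{m.mean_density:>9.2f}"
        f"{m.density_differential:>7.2f}{m.specificity_p:>11.3g}{m.fdr_p:>11.3g}"
    )

print()
for m in modules:
    planted = set(bundle.truth.module_genes.get(m.phenotype, []))
    jac = len(set(m.genes) & planted) / len(set(m.genes) | planted)
    print(f"{m.module_id}: Jaccard to planted truth = {jac:.2f}")
print()
print("A Jaccard of 1.00 means the anneal recovered the planted 10-gene")
print("block exactly; the specificity p of ~4.5e-3 is the smallest value")
print("achievable with 3 phenotype datasets among 12 (1/C(12,3)).")
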