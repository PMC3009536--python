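"""Generate a synthetic expression compendium with planted ground truth.

Builds the default desk-scale world: 12 expression datasets (300 genes x 30
samples) labeled with 4 leaf phenotypes from a small two-level ontology,
three 10-gene modules planted with within-module correlation r = 0.9 in
their phenotype's datasets, noisy gene-phenotype annotations, PPI and GO
tables with elevated sharing inside modules, and phenotype-labeled ChIP
target sets.
"""

from phenomod import SimulationConfig, simulate_collection

bundle = simulate_collection(SimulationConfig(seed=1), out_dir="scratch/example_inputs")

print(f"datasets        : {len(bundle.datasets)}")
print(f"genes/dataset   : {bundle.datasets[0].matrix.shape[0]}")
print(f"ontology terms  : {sorted(bundle.ontology.terms)}")
for pheno, genes in sorted(bundle.truth.module_genes.items()):
    carriers = bundle.truth.module_datasets[pheno]
    print(f"planted module  : {pheno} ({len(genes)} genes, dense in {carriers})")
print(f"known annotations: {len(bundle.annotations.associations)}")
print(f"PPI edges       : {len(bundle.ppi)}")
print(f"ChIP datasets   : {[c.id for c in bundle.chips]}")
print()
print("Each planted module is the ground truth the downstream stages must")
print("recover; the files in scratch/example_inputs/ are the exact formats")
print("the discovery, classification, and concordance stages consume.")
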