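"""Call pleiotropic genes against the phenotype ontology.

A gene is pleiotropic when it carries two phenotypes neither of which is
an ancestor of the other under PAR edges: a disease plus its own parent
category does not count.  Merging predicted associations shows which genes
become pleiotropic only through predictions ("novel") and which already-
pleiotropic genes gain a phenotype incomparable to all prior annotations
("new case").
"""

from phenomod import (
    GenePhenotypeDB,
    PhenotypeOntology,
    pleiotropy_census,
    propagate_annotations,
)

# Two disease branches plus a tissue branch.
ontology = PhenotypeOntology(
    edges={
        ("leukemia", "immunoproliferative", "PAR"),
        ("lymphoma", "immunoproliferative", "PAR"),
        ("glioma", "nervous_system_disorder", "PAR"),
        ("brain", "tissue", "PAR"),
    }
)

known = propagate_annotations(
    GenePhenotypeDB(
        {
            ("TAL1_like", "leukemia", "known"),       # + its parent only
            ("DUAL", "leukemia", "known"),
            ("DUAL", "glioma", "known"),              # two distinct branches
            ("SINGLE", "lymphoma", "known"),
        }
    ),
    ontology,
)
predictions = GenePhenotypeDB({("SINGLE", "glioma", "predicted"),
                               ("DUAL", "brain", "predicted")})

report = pleiotropy_census(known, ontology, predictions=predictions)

print(f"genes in census      : {report.n_genes}")
print(f"fraction pleiotropic : {report.fraction_pleiotropic:.2f}")
for gene, pair in sorted(report.pleiotropic.items()):
    print(f"  {gene}: witnessed by {pair}")
print(f"novel pleiotropic    : {sorted(report.novel_pleiotropic)}")
print(f"new cases            : {sorted(report.new_cases)}")
print()
print("TAL1_like is annotated with leukemia and (by propagation) its parent")
print("only, so it is not pleiotropic; DUAL spans two branches and is; the")
print("glioma prediction makes SINGLE newly pleiotropic, and the brain")
print("prediction gives the already-pleiotropic DUAL a new case.")
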