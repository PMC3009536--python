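"""Gene pleiotropy against the phenotype ontology's parental structure.

A gene is pleiotropic when it is annotated with at least two phenotypes,
neither of which is a descendant of the other under PAR edges.  An ancestor/
descendant pair (e.g. a disease and its parent category) does not count as
two distinct associations.  When predicted associations are merged in, the
census also reports genes that become pleiotropic only through predictions
and previously pleiotropic genes that gain a phenotype incomparable to all
their prior annotations (a "new case" of pleiotropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from phenomod.ontology import GenePhenotypeDB, PhenotypeOntology


@dataclass
class PleiotropyReport:
    fraction_pleiotropic: float
    pleiotropic: dict[str, tuple[str, str]]  # gene -> one witnessing pair
    novel_pleiotropic: set[str]
    new_cases: set[str]
    n_genes: int

    def __post_init__(self) -> None:
        assert not (self.novel_pleiotropic & self.new_cases)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["gene\tpleiotropic\twitness_a\twitness_b\tnovel\tnew_case"]
        genes = sorted(
            set(self.pleiotropic) | self.novel_pleiotropic | self.new_cases
        )
        for g in genes:
            pair = self.pleiotropic.get(g, ("", ""))
            lines.append(
                f"{g}\t{int(g in self.pleiotropic)}\t{pair[0]}\t{pair[1]}\t"
                f"{int(g in self.novel_pleiotropic)}\t{int(g in self.new_cases)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _incomparable_pair(
    phenotypes: Iterable[str], ontology: PhenotypeOntology
) -> tuple[str, str] | None:
    """First pair (sorted order) with neither term a descendant of the other."""
    terms = sorted(set(phenotypes))
    for i, p in enumerate(terms):
        for q in terms[i + 1:]:
            if not ontology.is_descendant(p, q) and not ontology.is_descendant(q, p):
                return (p, q)
    return None


def is_pleiotropic(
    gene: str,
    db: GenePhenotypeDB,
    ontology: PhenotypeOntology,
    include_predicted: bool = False,
    restrict_to: set[str] | None = None,
) -> tuple[bool, tuple[str, str] | None]:
    """Whether the gene carries two mutually non-ancestral phenotypes.

    ``db`` should already be propagated to ancestors.  ``restrict_to``
    limits the census to a phenotype subset (e.g. disease terms only).
    """
    phenos = db.phenotypes_of(gene, provenance=None if include_predicted else "known")
    if restrict_to is not None:
        phenos &= restrict_to
    pair = _incomparable_pair(phenos, ontology)
    return (pair is not None, pair)


def pleiotropy_census(
    db: GenePhenotypeDB,
    ontology: PhenotypeOntology,
    predictions: GenePhenotypeDB | None = None,
    gene_universe: Iterable[str] | None = None,
    restrict_to: set[str] | None = None,
) -> PleiotropyReport:
    """Fraction of pleiotropic genes, plus prediction-driven novelty accounting.

    The fraction is computed over ``gene_universe`` (default: genes with any
    known annotation) using known associations only.  With ``predictions``
    merged (and ancestor-propagated), ``novel_pleiotropic`` collects genes
    pleiotropic only under the merged set; ``new_cases`` collects genes that
    were already pleiotropic and gain a predicted phenotype incomparable to
    every previously annotated phenotype.
    """
    genes = set(gene_universe) if gene_universe is not None else db.genes()
    pleio: dict[str, tuple[str, str]] = {}
    for g in sorted(genes):
        ok, pair = is_pleiotropic(g, db, ontology, restrict_to=restrict_to)
        if ok:
            pleio[g] = pair

    novel: set[str] = set()
    new_cases: set[str] = set()
    if predictions is not None:
        from phenomod.ontology import propagate_annotations

        merged = propagate_annotations(db.merged_with(predictions), ontology)
        for g in sorted(genes | predictions.genes()):
            known = db.phenotypes_of(g, provenance="known")
            if restrict_to is not None:
                known &= restrict_to
            merged_ph = merged.phenotypes_of(g)
            if restrict_to is not None:
                merged_ph &= restrict_to
            if g not in pleio:
                if _incomparable_pair(merged_ph, ontology) is not None:
                    novel.add(g)
            else:
                gained = merged_ph - known
                for q in sorted(gained):
                    if all(
                        not ontology.is_descendant(q, p)
                        and not ontology.is_descendant(p, q)
                        and p != q
                        for p in known
                    ):
                        new_cases.add(g)
                        break

    return PleiotropyReport(
        fraction_pleiotropic=len(pleio) / len(genes) if genes else 0.0,
        pleiotropic=pleio,
        novel_pleiotropic=novel,
        new_cases=new_cases,
        n_genes=len(genes),
    )
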