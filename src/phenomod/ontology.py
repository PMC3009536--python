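"""Phenotype ontology graph and the gene-phenotype annotation database.

The ontology is a typed edge list over phenotype terms.  ``PAR`` edges point
from a child term to a parent term and must form a DAG; every other relation
type in :data:`RELATED_TYPES` marks two terms as *related* (a symmetric,
one-hop notion covering similarity and synonymy).  Gene-phenotype
associations are propagated upward along PAR edges so that a gene annotated
with a specific term is also annotated with every ancestor of that term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

#: Relation labels treated as "related" (one-hop, symmetric).
RELATED_TYPES = frozenset({"RB", "RL", "RN", "RO", "RQ", "RU", "SY"})

#: Parent-of relation label; the PAR subgraph must be acyclic.
PAR = "PAR"


class OntologyError(ValueError):
    """Raised for unknown terms or a cyclic parental subgraph."""


@dataclass
class PhenotypeOntology:
    """Typed phenotype graph: a PAR DAG plus symmetric related edges.

    Parameters
    ----------
    terms:
        All phenotype identifiers, including isolated ones.
    edges:
        ``(child, parent_or_neighbor, relation)`` triples with relation in
        ``{PAR} | RELATED_TYPES``.
    """

    terms: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.terms = set(self.terms)
        self.edges = set(self.edges)
        for child, parent, rel in self.edges:
            if rel != PAR and rel not in RELATED_TYPES:
                raise OntologyError(f"unknown relation type {rel!r}")
            self.terms.update((child, parent))
        self._par = nx.DiGraph()
        self._par.add_nodes_from(self.terms)
        self._par.add_edges_from(
            (c, p) for c, p, r in self.edges if r == PAR
        )
        if not nx.is_directed_acyclic_graph(self._par):
            cycle = nx.find_cycle(self._par)
            raise OntologyError(
                f"PAR edges contain a cycle (e.g. through {cycle[0][0]!r}); "
                "parental traces must terminate at a root"
            )
        self._related: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, other, rel in self.edges:
            if rel in RELATED_TYPES:
                self._related[child].add(other)
                self._related[other].add(child)

    def _require(self, term: str) -> None:
        if term not in self.terms:
            raise OntologyError(f"unknown phenotype term {term!r}")

    def add_term(self, term: str) -> None:
        """Add an isolated term (used for annotation terms missing upstream)."""
        if term not in self.terms:
            self.terms.add(term)
            self._par.add_node(term)
            self._related[term] = set()

    def parental_set(self, p: str) -> set[str]:
        """All ancestors of ``p`` along PAR edges (the trace to the root)."""
        self._require(p)
        return set(nx.descendants(self._par, p))

    def related_set(self, p: str) -> set[str]:
        """Terms one related-type edge away from ``p`` (either direction)."""
        self._require(p)
        return set(self._related[p]) - {p}

    def is_descendant(self, a: str, b: str) -> bool:
        """True iff ``a`` lies strictly below ``b`` in the PAR hierarchy."""
        self._require(a)
        self._require(b)
        return b in self.parental_set(a)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeOntology":
        """Load from a 3-column TSV ``child<TAB>parent<TAB>relation``.

        Lines starting with ``#`` are comments.
        """
        edges = set()
        terms: set[str] = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                terms.add(parts[0])
                continue
            if len(parts) != 3:
                raise OntologyError(f"malformed ontology line: {line!r}")
            edges.add((parts[0], parts[1], parts[2]))
        return cls(terms=terms, edges=edges)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{c}\t{p}\t{r}" for c, p, r in sorted(self.edges)]
        linked = {t for c, p, _ in self.edges for t in (c, p)}
        lines.extend(sorted(self.terms - linked))
        Path(path).write_text("\n".join(lines) + "\n")


# Module-level functional aliases matching the operation surface.

def parental_set(ontology: PhenotypeOntology, p: str) -> set[str]:
    return ontology.parental_set(p)


def related_set(ontology: PhenotypeOntology, p: str) -> set[str]:
    return ontology.related_set(p)


def is_descendant(ontology: PhenotypeOntology, a: str, b: str) -> bool:
    return ontology.is_descendant(a, b)


@dataclass
class GenePhenotypeDB:
    """Gene-phenotype associations with a ``known``/``predicted`` provenance flag.

    ``associations`` is a set of ``(gene, phenotype, provenance)`` triples;
    set semantics make duplicate entries impossible.
    """

    associations: set[tuple[str, str, str]] = field(default_factory=set)

    PROVENANCES = ("known", "predicted")

    def __post_init__(self) -> None:
        self.associations = set(self.associations)
        for g, p, prov in self.associations:
            if prov not in self.PROVENANCES:
                raise ValueError(f"bad provenance {prov!r} for ({g}, {p})")

    def add(self, gene: str, phenotype: str, provenance: str = "known") -> None:
        if provenance not in self.PROVENANCES:
            raise ValueError(f"bad provenance {provenance!r}")
        self.associations.add((gene, phenotype, provenance))

    def genes(self) -> set[str]:
        return {g for g, _, _ in self.associations}

    def phenotypes_of(
        self, gene: str, provenance: str | None = None
    ) -> set[str]:
        return {
            p
            for g, p, prov in self.associations
            if g == gene and (provenance is None or prov == provenance)
        }

    def known_genes(self, phenotype: str) -> set[str]:
        """G_p: genes with a known association to ``phenotype``."""
        return {
            g for g, p, prov in self.associations
            if p == phenotype and prov == "known"
        }

    def merged_with(self, other: "GenePhenotypeDB") -> "GenePhenotypeDB":
        return GenePhenotypeDB(self.associations | other.associations)

    def sync_ontology(self, ontology: PhenotypeOntology) -> None:
        """Auto-add annotation terms missing from the ontology, with a warning."""
        missing = sorted(
            {p for _, p, _ in self.associations} - ontology.terms
        )
        if missing:
            warnings.warn(
                f"{len(missing)} annotation phenotype(s) absent from the "
                f"ontology were added as isolated terms: {missing[:5]}...",
                stacklevel=2,
            )
            for term in missing:
                ontology.add_term(term)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePhenotypeDB":
        """Load ``gene<TAB>phenotype[<TAB>provenance]`` (default ``known``)."""
        assoc = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                assoc.add((parts[0], parts[1], "known"))
            elif len(parts) == 3:
                assoc.add((parts[0], parts[1], parts[2]))
            else:
                raise ValueError(f"malformed annotation line: {line!r}")
        return cls(assoc)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{g}\t{p}\t{prov}" for g, p, prov in sorted(self.associations)]
        Path(path).write_text("\n".join(lines) + "\n")


def propagate_annotations(
    db: GenePhenotypeDB, ontology: PhenotypeOntology
) -> GenePhenotypeDB:
    """Close every association upward along PAR edges.

    For each ``(gene, p, prov)``, adds ``(gene, q, prov)`` for every ancestor
    ``q`` of ``p``.  Idempotent and monotone (output is a superset of input).
    """
    db.sync_ontology(ontology)
    out = set(db.associations)
    for gene, pheno, prov in db.associations:
        for anc in ontology.parental_set(pheno):
            out.add((gene, anc, prov))
    return GenePhenotypeDB(out)
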