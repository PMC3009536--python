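import numpy as np
import pytest

from phenomod.coexpression import ExpressionDataset
from phenomod.ontology import GenePhenotypeDB, PhenotypeOntology


@pytest.fixture
def diamond_ontology():
    """a -> {b, d} -> c, plus related edges a~x (SY) and a~y (RB)."""
    return PhenotypeOntology(
        edges={
            ("a", "b", "PAR"),
            ("a", "d", "PAR"),
            ("b", "c", "PAR"),
            ("d", "c", "PAR"),
            ("a", "x", "SY"),
            ("a", "y", "RB"),
        }
    )


@pytest.fixture
def two_branch_ontology():
    """Two disjoint branches: {p1, p2} -> r1 and {q1} -> r2; p1 ~ p2 related."""
    return PhenotypeOntology(
        edges={
            ("p1", "r1", "PAR"),
            ("p2", "r1", "PAR"),
            ("q1", "r2", "PAR"),
            ("p1", "p2", "RO"),
        }
    )


def random_dag_edges(rng, n_terms):
    """Random PAR DAG on t0..t{n-1}; edges only from lower to higher index."""
    terms = [f"t{i}" for i in range(n_terms)]
    edges = set()
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < 0.15:
                edges.add((terms[i], terms[j], "PAR"))
    return terms, edges


def make_dataset(rng, ds_id, genes, n_samples=10, phenotypes=()):
    return ExpressionDataset(
        id=ds_id,
        matrix=rng.standard_normal((len(genes), n_samples)),
        genes=tuple(genes),
        phenotypes=set(phenotypes),
    )
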