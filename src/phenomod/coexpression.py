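"""Per-dataset unweighted coexpression networks and module density.

Each expression dataset (genes x samples) yields one network: Pearson
correlation over samples for every gene pair restricted to a shared gene
universe, with the top ``edge_budget`` pairs (ranked by signed r, optionally
|r|) kept as unweighted edges.  Module density in a network is the fraction
of realized edges among all pairs of the module's genes; a module's
"dense dataset set" collects the datasets in which that fraction clears a
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Inclusion rule for datasets: minimum number of experimental samples.
MIN_SAMPLES = 8


@dataclass
class ExpressionDataset:
    """One gene x sample expression matrix with phenotype labels."""

    id: str
    matrix: np.ndarray  # genes x samples
    genes: tuple[str, ...]
    phenotypes: set[str] = field(default_factory=set)
    min_samples: int = MIN_SAMPLES

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.genes = tuple(self.genes)
        self.phenotypes = set(self.phenotypes)
        if self.matrix.ndim != 2:
            raise ValueError(f"{self.id}: matrix must be 2-D")
        if self.matrix.shape[0] != len(self.genes):
            raise ValueError(
                f"{self.id}: {self.matrix.shape[0]} rows but "
                f"{len(self.genes)} gene ids"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.id}: duplicate gene identifiers")
        if any(not g for g in self.genes):
            raise ValueError(f"{self.id}: empty gene identifier")
        if self.matrix.shape[1] < self.min_samples:
            raise ValueError(
                f"{self.id}: {self.matrix.shape[1]} samples < required "
                f"minimum of {self.min_samples}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        dataset_id: str | None = None,
        phenotypes: Iterable[str] = (),
        min_samples: int = MIN_SAMPLES,
    ) -> "ExpressionDataset":
        """Read a TSV whose first column is ``gene``, remaining columns samples."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            id=dataset_id or Path(path).stem,
            matrix=df.to_numpy(dtype=float),
            genes=tuple(str(g) for g in df.index),
            phenotypes=set(phenotypes),
            min_samples=min_samples,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.matrix,
            index=list(self.genes),
            columns=[f"s{j + 1}" for j in range(self.n_samples)],
        )
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class CoexpressionNetwork:
    """Unweighted coexpression graph over a shared gene universe."""

    dataset_id: str
    edges: frozenset[tuple[str, str]]
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        self.edges = frozenset(tuple(sorted(e)) for e in self.edges)
        self.gene_universe = frozenset(self.gene_universe)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in self.gene_universe or b not in self.gene_universe:
                raise ValueError(f"edge ({a}, {b}) outside the gene universe")

    def adjacency(self, gene_order: Sequence[str]) -> np.ndarray:
        """Boolean adjacency matrix in the given gene order."""
        index = {g: i for i, g in enumerate(gene_order)}
        A = np.zeros((len(gene_order), len(gene_order)), dtype=bool)
        for a, b in self.edges:
            ia, ib = index.get(a), index.get(b)
            if ia is not None and ib is not None:
                A[ia, ib] = A[ib, ia] = True
        return A

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{a}\t{b}" for a, b in sorted(self.edges)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, dataset_id: str, gene_universe: Iterable[str]
    ) -> "CoexpressionNetwork":
        edges = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            edges.add((a, b))
        return cls(dataset_id, frozenset(edges), frozenset(gene_universe))


def shared_gene_universe(collection: Sequence[ExpressionDataset]) -> set[str]:
    """Genes present in every dataset of the collection."""
    if not collection:
        raise ValueError("need at least one dataset")
    universe = set(collection[0].genes)
    for ds in collection[1:]:
        universe &= set(ds.genes)
    if not universe:
        raise ValueError(
            "no gene is shared by all datasets; inspect gene identifier "
            "conventions across the collection"
        )
    return universe


def build_network(
    ds: ExpressionDataset,
    universe: Iterable[str],
    edge_budget: int,
    abs_corr: bool = False,
) -> CoexpressionNetwork:
    """Threshold the Pearson correlation matrix to the top ``edge_budget`` pairs.

    Ranking uses signed r by default (positive coexpression); ``abs_corr=True``
    ranks by |r|.  Genes with zero variance or any missing value are dropped
    from the ranking with a warning.  Ties at the budget boundary are broken
    by lexicographic gene-pair order so the network is reproducible.
    """
    universe = set(universe)
    if not universe <= set(ds.genes):
        raise ValueError(f"{ds.id}: universe contains genes absent from dataset")
    if edge_budget < 1:
        raise ValueError("edge_budget must be >= 1")

    order = sorted(universe)
    idx = [ds.genes.index(g) for g in order]
    X = ds.matrix[idx, :]

    bad_nan = np.isnan(X).any(axis=1)
    bad_var = ~bad_nan & (np.nanstd(X, axis=1) == 0)
    keep = ~(bad_nan | bad_var)
    dropped = [g for g, k in zip(order, keep) if not k]
    if dropped:
        warnings.warn(
            f"{ds.id}: {len(dropped)} gene(s) with missing values or zero "
            f"variance excluded from the network: {dropped[:5]}",
            stacklevel=2,
        )
    kept_genes = [g for g, k in zip(order, keep) if k]
    Xk = X[keep]
    n = len(kept_genes)
    if n < 2:
        return CoexpressionNetwork(ds.id, frozenset(), frozenset(universe))

    R = np.corrcoef(Xk)
    iu, ju = np.triu_indices(n, k=1)
    score = np.abs(R[iu, ju]) if abs_corr else R[iu, ju]

    # Stable rank: score descending, then lexicographic gene pair.
    pairs = sorted(
        zip(score, iu, ju), key=lambda t: (-t[0], kept_genes[t[1]], kept_genes[t[2]])
    )
    top = pairs[: min(edge_budget, len(pairs))]
    edges = frozenset(
        tuple(sorted((kept_genes[i], kept_genes[j]))) for _, i, j in top
    )
    return CoexpressionNetwork(ds.id, edges, frozenset(universe))


def module_density(net: CoexpressionNetwork, genes: Iterable[str]) -> float:
    """Fraction of realized edges among all pairs of ``genes`` in one network."""
    gene_set = set(genes)
    if len(gene_set) < 2:
        raise ValueError("module density is undefined for fewer than 2 genes")
    if not gene_set <= net.gene_universe:
        raise ValueError("module contains genes outside the network universe")
    k = len(gene_set)
    inside = sum(1 for a, b in net.edges if a in gene_set and b in gene_set)
    return inside / math.comb(k, 2)


def dense_dataset_set(
    nets: Sequence[CoexpressionNetwork],
    genes: Iterable[str],
    tau_dense: float = 0.66,
) -> set[str]:
    """Dataset ids whose network carries the module at density >= tau_dense."""
    if not 0 < tau_dense <= 1:
        raise ValueError("tau_dense must be in (0, 1]")
    gene_set = set(genes)
    return {
        net.dataset_id
        for net in nets
        if module_density(net, gene_set) >= tau_dense
    }


def load_collection(
    manifest_path: str | Path, min_samples: int = MIN_SAMPLES
) -> list[ExpressionDataset]:
    """Load datasets from a manifest TSV ``dataset_id<TAB>path<TAB>ph1;ph2``.

    Relative paths are resolved against the manifest's directory.
    """
    base = Path(manifest_path).parent
    out = []
    for line in Path(manifest_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ds_id, rel, phenos = line.split("\t")
        path = Path(rel)
        if not path.is_absolute():
            path = base / path
        out.append(
            ExpressionDataset.from_tsv(
                path,
                dataset_id=ds_id,
                phenotypes={p for p in phenos.split(";") if p},
                min_samples=min_samples,
            )
        )
    return out
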