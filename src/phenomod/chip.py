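"""Concordance between phenotype-labeled TF binding and module phenotypes.

Each ChIP dataset supplies a transcription factor, its bound target genes,
and the phenotype(s) under which binding was assayed.  For a phenotype seen
in both the ChIP data and the module collection, every module gets an
upper-tail hypergeometric binding-enrichment p-value; modules whose
discovery phenotype is the ChIP phenotype or one related-edge away form the
"related" group, the rest the "unrelated" group, and a one-sided
Mann-Whitney test asks whether related modules are more enriched (smaller
p-values).  Benjamini-Hochberg across phenotypes controls the FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, mannwhitneyu

from phenomod.mosa import PhenotypeModule, bh_adjust
from phenomod.ontology import PhenotypeOntology


@dataclass
class ChIPDataset:
    id: str
    tf: str
    targets: set[str]
    phenotypes: set[str]

    def __post_init__(self) -> None:
        self.targets = set(self.targets)
        self.phenotypes = set(self.phenotypes)
        if not self.targets:
            raise ValueError(f"ChIP dataset {self.id!r} has no targets")


@dataclass
class ConcordanceResult:
    chip_phenotype: str
    related_module_pvalues: list[float]
    unrelated_module_pvalues: list[float]
    mw_pvalue: float
    fdr_adjusted: float
    significant: bool


def module_binding_pvalue(
    module_genes: set[str], targets: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric P(overlap >= observed) in the shared universe."""
    if not (set(module_genes) <= set(universe)):
        raise ValueError("module genes must lie within the gene universe")
    targets_in = set(targets) & set(universe)
    overlap = len(set(module_genes) & targets_in)
    return float(
        hypergeom.sf(overlap - 1, len(universe), len(targets_in), len(module_genes))
    )


def split_modules_by_relatedness(
    modules: Sequence[PhenotypeModule],
    chip_phenotype: str,
    ontology: PhenotypeOntology,
) -> tuple[list[PhenotypeModule], list[PhenotypeModule]]:
    """Partition modules into phenotype-related and unrelated groups."""
    related_terms = {chip_phenotype} | ontology.related_set(chip_phenotype)
    related, unrelated = [], []
    for m in modules:
        (related if m.phenotype in related_terms else unrelated).append(m)
    return related, unrelated


def preferential_binding_test(
    related_pvals: Sequence[float], unrelated_pvals: Sequence[float]
) -> float:
    """One-sided Mann-Whitney p: related enrichment p-values stochastically smaller."""
    if not len(related_pvals):
        raise ValueError("related group is empty")
    if not len(unrelated_pvals):
        raise ValueError("unrelated group is empty")
    # Exact null distribution whenever tie-free and small enough to afford:
    # the normal approximation is slightly anticonservative at these sizes.
    no_ties = len(set(related_pvals) | set(unrelated_pvals)) == len(
        related_pvals
    ) + len(unrelated_pvals)
    method = (
        "exact"
        if no_ties and len(related_pvals) + len(unrelated_pvals) <= 60
        else "asymptotic"
    )
    res = mannwhitneyu(
        related_pvals, unrelated_pvals, alternative="less", method=method
    )
    return float(res.pvalue)


def _module_pvalues(
    modules: Sequence[PhenotypeModule],
    chips: Sequence[ChIPDataset],
    universe: set[str],
    pooling: str,
) -> list[float]:
    """Per-module binding p against a phenotype's ChIP datasets.

    ``pooling="tf_min"`` (default): per TF target set, keep the module's
    minimum p.  ``pooling="union"``: one test against the union of targets.
    ``pooling="pairs"`` is handled by the caller (all TF-module pairs).
    """
    out = []
    for m in modules:
        genes = set(m.genes) & universe
        if len(genes) < 1:
            out.append(1.0)
            continue
        if pooling == "union":
            pooled = set().union(*(c.targets for c in chips))
            out.append(module_binding_pvalue(genes, pooled, universe))
        else:
            out.append(
                min(
                    module_binding_pvalue(genes, c.targets, universe)
                    for c in chips
                )
            )
    return out


def concordance_screen(
    modules: Sequence[PhenotypeModule],
    chips: Sequence[ChIPDataset],
    ontology: PhenotypeOntology,
    universe: Iterable[str],
    fdr_alpha: float = 0.05,
    pooling: str = "tf_min",
) -> list[ConcordanceResult]:
    """Per shared ChIP phenotype, test for preferential binding to related modules.

    Phenotypes with an empty related or unrelated module group are skipped
    with a warning.  BH correction runs across the tested phenotypes.
    """
    universe = set(universe)
    module_phenos = {m.phenotype for m in modules}
    chip_phenos = sorted(
        {p for c in chips for p in c.phenotypes} & module_phenos
    )
    if not chip_phenos:
        raise ValueError(
            "no ChIP phenotype is shared with the module phenotypes"
        )
    partial: list[tuple[str, list[float], list[float], float]] = []
    for pheno in chip_phenos:
        pheno_chips = [c for c in chips if pheno in c.phenotypes]
        related, unrelated = split_modules_by_relatedness(modules, pheno, ontology)
        if not related or not unrelated:
            warnings.warn(
                f"phenotype {pheno!r}: empty "
                f"{'related' if not related else 'unrelated'} module group; skipped",
                stacklevel=2,
            )
            continue
        if pooling == "pairs":
            rel_p = [
                module_binding_pvalue(set(m.genes) & universe, c.targets, universe)
                for m in related
                for c in pheno_chips
            ]
            unr_p = [
                module_binding_pvalue(set(m.genes) & universe, c.targets, universe)
                for m in unrelated
                for c in pheno_chips
            ]
        else:
            rel_p = _module_pvalues(related, pheno_chips, universe, pooling)
            unr_p = _module_pvalues(unrelated, pheno_chips, universe, pooling)
        mw = preferential_binding_test(rel_p, unr_p)
        partial.append((pheno, rel_p, unr_p, mw))

    if not partial:
        return []
    adj = bh_adjust([t[3] for t in partial])
    return [
        ConcordanceResult(
            chip_phenotype=pheno,
            related_module_pvalues=rel_p,
            unrelated_module_pvalues=unr_p,
            mw_pvalue=mw,
            fdr_adjusted=float(a),
            significant=bool(a < fdr_alpha),
        )
        for (pheno, rel_p, unr_p, mw), a in zip(partial, adj)
    ]


def enrichment_ratio_profile(
    related_pvals: Sequence[float],
    unrelated_pvals: Sequence[float],
    bins: Sequence[float],
    cap: float = 10.0,
) -> list[float]:
    """Per-bin log2 ratio of the two p-value distributions' relative frequencies.

    ``bins`` are edges partitioning (0, 1]; a bin empty on one side yields a
    capped +/-``cap`` sentinel (0.0 when empty on both) so profiles stay
    finite for display.
    """
    rel = np.asarray(related_pvals, dtype=float)
    unr = np.asarray(unrelated_pvals, dtype=float)
    edges = np.asarray(bins, dtype=float)
    rel_counts, _ = np.histogram(rel, bins=edges)
    unr_counts, _ = np.histogram(unr, bins=edges)
    rel_frac = rel_counts / max(len(rel), 1)
    unr_frac = unr_counts / max(len(unr), 1)
    out = []
    for rf, uf in zip(rel_frac, unr_frac):
        if rf == 0 and uf == 0:
            out.append(0.0)
        elif uf == 0:
            out.append(cap)
        elif rf == 0:
            out.append(-cap)
        else:
            out.append(
                float(np.clip(math.log2(rf / uf), -cap, cap))
            )
    return out


def load_chip_gmt(
    gmt_path: str | Path, pheno_path: str | Path
) -> list[ChIPDataset]:
    """GMT file ``tf_id<TAB>description<TAB>gene...`` plus ``tf_id<TAB>phenotype`` sidecar."""
    phenos: dict[str, set[str]] = {}
    for line in Path(pheno_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tf_id, pheno = line.split("\t")
        phenos.setdefault(tf_id, set()).add(pheno)
    chips = []
    for line in Path(gmt_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        tf_id, desc, targets = parts[0], parts[1], parts[2:]
        chips.append(
            ChIPDataset(
                id=tf_id,
                tf=desc or tf_id,
                targets=set(targets),
                phenotypes=phenos.get(tf_id, set()),
            )
        )
    return chips


def write_chip_gmt(
    chips: Sequence[ChIPDataset], gmt_path: str | Path, pheno_path: str | Path
) -> None:
    gmt = [
        "\t".join([c.id, c.tf, *sorted(c.targets)]) for c in chips
    ]
    Path(gmt_path).write_text("\n".join(gmt) + "\n")
    side = [
        f"{c.id}\t{p}" for c in chips for p in sorted(c.phenotypes)
    ]
    Path(pheno_path).write_text("\n".join(side) + "\n")


def write_concordance(
    results: Sequence[ConcordanceResult], path: str | Path
) -> None:
    lines = ["chip_phenotype\tn_related\tn_unrelated\tmw_pvalue\tfdr_adjusted\tsignificant"]
    for r in results:
        lines.append(
            f"{r.chip_phenotype}\t{len(r.related_module_pvalues)}\t"
            f"{len(r.unrelated_module_pvalues)}\t{r.mw_pvalue:.6g}\t"
            f"{r.fdr_adjusted:.6g}\t{int(r.significant)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
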