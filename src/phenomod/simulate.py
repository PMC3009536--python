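"""Synthetic input bundles with planted, exported ground truth.

The generator emulates the structure of a curated expression-compendium
study at desk scale: a collection of gene x sample matrices labeled with
phenotype terms from a small two-level ontology, gene-phenotype annotations
with text-mining-style noise, a PPI edge list and GO annotations with
elevated sharing inside planted modules, and phenotype-labeled ChIP target
sets that overlap phenotype-matched modules.

Planted coexpression follows a single-factor model: inside an active
dataset, member genes are ``sqrt(r) * z + sqrt(1 - r) * eps`` for a shared
per-sample latent ``z``, giving expected pairwise Pearson correlation r.
Everything is reproducible from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from phenomod.chip import ChIPDataset, write_chip_gmt
from phenomod.coexpression import ExpressionDataset
from phenomod.mosa import PhenotypeModule
from phenomod.ontology import (
    GenePhenotypeDB,
    PhenotypeOntology,
    propagate_annotations,
)


@dataclass
class PlantedModule:
    """One ground-truth module: who, where, and how strongly coexpressed."""

    size: int = 10
    phenotype: str = "PH1"
    r: float = 0.9
    dataset_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.r < 1:
            raise ValueError("within-module correlation r must be in [0, 1)")
        if not 0 < self.dataset_fraction <= 1:
            raise ValueError("dataset_fraction must be in (0, 1]")
        if self.size < 2:
            raise ValueError("planted module size must be >= 2")


@dataclass
class SimulationConfig:
    """Desk-scale defaults: the full pipeline runs in minutes on one CPU."""

    n_genes: int = 300
    n_datasets: int = 12
    n_samples: int = 30
    n_phenotypes: int = 4
    ontology_depth: int = 2
    planted: tuple[PlantedModule, ...] = (
        PlantedModule(10, "PH1", 0.9, 1.0),
        PlantedModule(10, "PH2", 0.9, 1.0),
        PlantedModule(10, "PH3", 0.9, 1.0),
    )
    related_edges: tuple[tuple[str, str, str], ...] = ()
    annotation_fp: float = 0.05
    annotation_fn: float = 0.1
    ppi_within: float = 0.3
    ppi_background: float = 0.01
    go_background_terms: int = 40
    go_terms_per_gene: int = 2
    go_module_terms: int = 2
    go_module_term_prob: float = 0.8
    chip_concordance: float = 0.8
    chip_extra_targets: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("datasets must have at least 8 samples")
        for rate in (
            self.annotation_fp,
            self.annotation_fn,
            self.ppi_within,
            self.ppi_background,
            self.chip_concordance,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for m in self.planted:
            if m.size > self.n_genes:
                raise ValueError(
                    f"planted module of size {m.size} exceeds the "
                    f"{self.n_genes}-gene universe"
                )


@dataclass
class GroundTruth:
    run_id: str
    module_genes: dict[str, list[str]]  # phenotype -> sorted planted gene list
    module_datasets: dict[str, list[str]]  # phenotype -> datasets carrying it
    true_associations: list[tuple[str, str]]
    pleiotropic_genes: list[str]
    concordant_chip_phenotypes: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["true_associations"] = [tuple(x) for x in d["true_associations"]]
        return cls(**d)


@dataclass
class SimulatedBundle:
    """In-memory inputs plus (optionally) the paths they were written to."""

    run_id: str
    datasets: list[ExpressionDataset]
    ontology: PhenotypeOntology
    annotations: GenePhenotypeDB
    ppi: set[tuple[str, str]]
    go_table: list[tuple[str, str, str]]  # (gene, term, subtree)
    chips: list[ChIPDataset]
    truth: GroundTruth
    paths: dict[str, str] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _build_ontology(config: SimulationConfig) -> tuple[PhenotypeOntology, list[str]]:
    """Two-level DAG: leaf phenotypes PAR-linked to alternating categories.

    Using two top-level categories (rather than one universal root) keeps
    disjoint branches genuinely disjoint, so negative training genes exist
    after ancestor propagation.
    """
    leaves = [f"PH{i + 1}" for i in range(config.n_phenotypes)]
    cats = ["CAT1", "CAT2"]
    edges = {
        (leaf, cats[i % 2], "PAR") for i, leaf in enumerate(leaves)
    }
    edges |= set(config.related_edges)
    return PhenotypeOntology(terms=set(leaves) | set(cats), edges=edges), leaves


def simulate_collection(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedBundle:
    """Generate the full input bundle; write it to ``out_dir`` when given."""
    rng = np.random.default_rng(config.seed)
    run_id = f"sim-seed{config.seed}"
    genes = _gene_names(config.n_genes)
    ontology, leaves = _build_ontology(config)

    # Datasets round-robin over leaf phenotypes.
    ds_phenos = [leaves[d % len(leaves)] for d in range(config.n_datasets)]
    ds_ids = [f"DS{d + 1:02d}" for d in range(config.n_datasets)]

    # Disjoint planted gene sets.
    shuffled = list(rng.permutation(genes))
    module_genes: dict[str, list[str]] = {}
    cursor = 0
    for m in config.planted:
        if m.phenotype not in leaves:
            raise ValueError(f"planted phenotype {m.phenotype!r} not in ontology")
        module_genes[m.phenotype] = sorted(shuffled[cursor: cursor + m.size])
        cursor += m.size

    # Which datasets carry each planted module.
    module_datasets: dict[str, list[str]] = {}
    for m in config.planted:
        carriers = [
            ds_ids[d] for d in range(config.n_datasets) if ds_phenos[d] == m.phenotype
        ]
        n_carry = max(1, round(m.dataset_fraction * len(carriers)))
        chosen = sorted(
            rng.choice(carriers, size=n_carry, replace=False).tolist()
        ) if carriers else []
        module_datasets[m.phenotype] = chosen

    gene_index = {g: i for i, g in enumerate(genes)}
    datasets = []
    for d, ds_id in enumerate(ds_ids):
        X = rng.standard_normal((config.n_genes, config.n_samples))
        for m in config.planted:
            if ds_id not in module_datasets[m.phenotype]:
                continue
            z = rng.standard_normal(config.n_samples)
            rows = [gene_index[g] for g in module_genes[m.phenotype]]
            X[rows, :] = np.sqrt(m.r) * z + np.sqrt(1.0 - m.r) * X[rows, :]
        datasets.append(
            ExpressionDataset(
                id=ds_id, matrix=X, genes=tuple(genes), phenotypes={ds_phenos[d]}
            )
        )

    # Annotations: planted membership with FN dropout, plus FP noise pairs.
    true_assoc = sorted(
        (g, m.phenotype) for m in config.planted for g in module_genes[m.phenotype]
    )
    assoc = set()
    for g, p in true_assoc:
        if rng.random() >= config.annotation_fn:
            assoc.add((g, p, "known"))
    for g in genes:
        for p in leaves:
            if rng.random() < config.annotation_fp:
                assoc.add((g, p, "known"))
    annotations = GenePhenotypeDB(assoc)

    # PPI: elevated density inside planted modules over sparse background.
    ppi: set[tuple[str, str]] = set()
    n = config.n_genes
    n_bg = rng.binomial(n * (n - 1) // 2, config.ppi_background)
    for _ in range(int(n_bg)):
        i, j = rng.choice(n, size=2, replace=False)
        ppi.add(tuple(sorted((genes[i], genes[j]))))
    for m in config.planted:
        mg = module_genes[m.phenotype]
        for a_i in range(len(mg)):
            for b_i in range(a_i + 1, len(mg)):
                if rng.random() < config.ppi_within:
                    ppi.add(tuple(sorted((mg[a_i], mg[b_i]))))

    # GO: per subtree, module-specific terms shared among members plus
    # uniform background terms; frequencies follow from the realized table.
    go_table: list[tuple[str, str, str]] = []
    for subtree in ("BP", "CC", "MF"):
        for m in config.planted:
            for t in range(config.go_module_terms):
                term = f"GO_{subtree}_{m.phenotype}_{t + 1}"
                for g in module_genes[m.phenotype]:
                    if rng.random() < config.go_module_term_prob:
                        go_table.append((g, term, subtree))
        bg_terms = [
            f"GO_{subtree}_BG{t + 1}" for t in range(config.go_background_terms)
        ]
        for g in genes:
            for _ in range(config.go_terms_per_gene):
                go_table.append((g, bg_terms[rng.integers(len(bg_terms))], subtree))
    go_table = sorted(set(go_table))

    # ChIP: one concordant TF per planted phenotype plus one non-concordant
    # TF labeled with a phenotype that has no planted module.
    chips = []
    for m in config.planted:
        mg = module_genes[m.phenotype]
        n_hit = max(1, round(config.chip_concordance * len(mg)))
        hits = sorted(rng.choice(mg, size=n_hit, replace=False).tolist())
        extras = sorted(
            rng.choice(genes, size=config.chip_extra_targets, replace=False).tolist()
        )
        chips.append(
            ChIPDataset(
                id=f"TF_{m.phenotype}",
                tf=f"TF_{m.phenotype}",
                targets=set(hits) | set(extras),
                phenotypes={m.phenotype},
            )
        )
    unplanted = [p for p in leaves if p not in module_genes]
    null_pheno = unplanted[0] if unplanted else leaves[0]
    null_targets = sorted(
        rng.choice(genes, size=config.chip_extra_targets, replace=False).tolist()
    )
    chips.append(
        ChIPDataset(
            id="TF_NULL",
            tf="TF_NULL",
            targets=set(null_targets),
            phenotypes={null_pheno},
        )
    )

    # Ground-truth pleiotropy from the noise-free associations.
    truth_db = propagate_annotations(
        GenePhenotypeDB({(g, p, "known") for g, p in true_assoc}), ontology
    )
    from phenomod.pleiotropy import is_pleiotropic

    pleio = sorted(
        g for g in {g for g, _ in true_assoc}
        if is_pleiotropic(g, truth_db, ontology)[0]
    )

    truth = GroundTruth(
        run_id=run_id,
        module_genes=module_genes,
        module_datasets=module_datasets,
        true_associations=true_assoc,
        pleiotropic_genes=pleio,
        concordant_chip_phenotypes=sorted(module_genes),
    )

    bundle = SimulatedBundle(
        run_id=run_id,
        datasets=datasets,
        ontology=ontology,
        annotations=annotations,
        ppi=ppi,
        go_table=go_table,
        chips=chips,
        truth=truth,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SimulatedBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    manifest_lines = []
    for ds in bundle.datasets:
        rel = f"expression/{ds.id}.tsv"
        ds.to_tsv(out / rel)
        manifest_lines.append(f"{ds.id}\t{rel}\t{';'.join(sorted(ds.phenotypes))}")
    (out / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    bundle.ontology.to_tsv(out / "ontology.tsv")
    bundle.annotations.to_tsv(out / "annotations.tsv")
    (out / "ppi.tsv").write_text(
        "\n".join(f"{a}\t{b}" for a, b in sorted(bundle.ppi)) + "\n"
    )
    (out / "go.tsv").write_text(
        "\n".join(f"{g}\t{t}\t{s}" for g, t, s in bundle.go_table) + "\n"
    )
    write_chip_gmt(bundle.chips, out / "chip.gmt", out / "chip_phenos.tsv")
    bundle.truth.to_json(out / "ground_truth.json")
    bundle.paths = {
        "manifest": str(out / "manifest.tsv"),
        "ontology": str(out / "ontology.tsv"),
        "annotations": str(out / "annotations.tsv"),
        "ppi": str(out / "ppi.tsv"),
        "go": str(out / "go.tsv"),
        "chip_gmt": str(out / "chip.gmt"),
        "chip_phenos": str(out / "chip_phenos.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
    }


def simulate_chip_concordance(
    n_related: int = 10,
    n_unrelated: int = 30,
    module_size: int = 10,
    n_genes: int = 300,
    target_size: int = 30,
    concordance: float = 0.8,
    seed: int = 0,
) -> tuple[list[PhenotypeModule], list[ChIPDataset], PhenotypeOntology, set[str]]:
    """A module collection plus one ChIP dataset for the concordance screen.

    ``n_related`` modules carry the ChIP phenotype ``PH_A``; the rest carry
    ``PH_B``.  The TF's target set contains a ``concordance`` fraction of
    each related module's genes plus random genes up to ``target_size``;
    ``concordance=0`` yields a uniform-target null instance.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    ontology = PhenotypeOntology(terms={"PH_A", "PH_B"}, edges=set())
    modules = []
    for i in range(n_related + n_unrelated):
        pheno = "PH_A" if i < n_related else "PH_B"
        mg = frozenset(
            rng.choice(genes, size=module_size, replace=False).tolist()
        )
        modules.append(
            PhenotypeModule(
                module_id=f"{pheno}_m{i + 1}",
                genes=mg,
                phenotype=pheno,
                dense_datasets=frozenset(),
                size=module_size,
                mean_density=float("nan"),
                density_differential=float("nan"),
                specificity_p=float("nan"),
                fdr_p=float("nan"),
            )
        )
    targets: set[str] = set()
    if concordance > 0:
        for m in modules[:n_related]:
            n_hit = round(concordance * module_size)
            if n_hit:
                targets |= set(
                    rng.choice(sorted(m.genes), size=n_hit, replace=False).tolist()
                )
    while len(targets) < target_size:
        targets.add(genes[int(rng.integers(n_genes))])
    chip = ChIPDataset(id="TF_A", tf="TF_A", targets=targets, phenotypes={"PH_A"})
    return modules, [chip], ontology, set(genes)


def _jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb) if (sa | sb) else 1.0


def truth_eval(
    truth: GroundTruth,
    run_id: str,
    modules: Sequence[PhenotypeModule] = (),
    predicted_associations: Iterable[tuple[str, str]] = (),
    called_pleiotropic: Iterable[str] | None = None,
    flagged_chip_phenotypes: Iterable[str] | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against planted truth.

    Returns a scorecard dict; fields for outputs not supplied are omitted.
    Raises if ``run_id`` does not match the truth's run id.
    """
    if run_id != truth.run_id:
        raise ValueError(
            f"outputs from run {run_id!r} scored against truth from "
            f"{truth.run_id!r}"
        )
    card: dict[str, float] = {}
    if modules:
        jac = []
        for pheno, planted in sorted(truth.module_genes.items()):
            best = max(
                (
                    _jaccard(m.genes, planted)
                    for m in modules
                    if m.phenotype == pheno
                ),
                default=0.0,
            )
            jac.append(best)
        card["module_jaccard_mean"] = float(np.mean(jac))
    preds = set(predicted_associations)
    if preds:
        true = set(truth.true_associations)
        tp = len(preds & true)
        card["association_precision"] = tp / len(preds)
        card["association_recall"] = tp / len(true) if true else 0.0
    if called_pleiotropic is not None:
        called = set(called_pleiotropic)
        true_p = set(truth.pleiotropic_genes)
        both = len(called & true_p)
        card["pleiotropy_precision"] = both / len(called) if called else 1.0
        card["pleiotropy_recall"] = both / len(true_p) if true_p else 1.0
    if flagged_chip_phenotypes is not None:
        flagged = set(flagged_chip_phenotypes)
        conc = set(truth.concordant_chip_phenotypes)
        card["concordance_hit_rate"] = (
            len(flagged & conc) / len(conc) if conc else 1.0
        )
    return card


def write_scorecard(card: Mapping[str, float], path: str | Path) -> None:
    lines = ["metric\tvalue"] + [
        f"{k}\t{card[k]:.6g}" for k in sorted(card)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
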