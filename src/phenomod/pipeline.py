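"""End-to-end orchestration: simulate -> discover -> classify -> pleiotropy -> chip.

Each stage reads only the outputs of earlier stages, derives its own seed
deterministically from the master seed and stage name, and writes into its
own subdirectory of the run directory.  Stage directories are immutable:
re-running a stage into an existing directory raises instead of silently
overwriting.  A run manifest records the configuration snapshot, stage
seeds, output paths, and content hashes, so two runs with the same master
seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from phenomod.chip import concordance_screen, write_concordance
from phenomod.classifier import (
    GO_SUBTREES,
    PhenotypeSkipped,
    assemble_features,
    build_training_split,
    train_and_predict,
)
from phenomod.coexpression import build_network, shared_gene_universe
from phenomod.mosa import MOSAConfig, filter_modules, mosa_search, write_modules
from phenomod.ontology import GenePhenotypeDB, propagate_annotations
from phenomod.pleiotropy import pleiotropy_census
from phenomod.simulate import (
    SimulatedBundle,
    SimulationConfig,
    simulate_collection,
    truth_eval,
    write_scorecard,
)

STAGES = ("simulate", "discover", "classify", "pleiotropy", "chip")

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {},  # SimulationConfig field overrides
    "network": {"edge_budget_fraction": 0.05, "abs_corr": False},
    "mosa": {},  # MOSAConfig field overrides
    "classify": {"trees": 500, "node_size": 10, "vote_cutoff": 0.5},
    "chip": {"fdr_alpha": 0.05, "pooling": "tf_min"},
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunManifest:
    config: dict[str, Any]
    master_seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, dict[str, str]]  # stage -> name -> path
    hashes: dict[str, str]  # path -> sha256
    version: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "master_seed": self.master_seed,
                    "stage_seeds": self.stage_seeds,
                    "outputs": self.outputs,
                    "hashes": self.hashes,
                    "version": self.version,
                },
                indent=1,
                sort_keys=True,
            )
        )


def _merge_config(user: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_dir(out: Path, stage: str) -> Path:
    d = out / stage
    if d.exists():
        raise FileExistsError(
            f"stage directory {d} already exists; stage outputs are immutable "
            "per run directory"
        )
    d.mkdir(parents=True)
    return d


def _go_tables(
    go_table: Sequence[tuple[str, str, str]]
) -> dict[str, tuple[dict[str, set[str]], dict[str, int]]]:
    """(gene -> terms, term -> carrier count) per GO subtree."""
    tables: dict[str, tuple[dict[str, set[str]], dict[str, int]]] = {}
    for subtree in GO_SUBTREES:
        ann: dict[str, set[str]] = {}
        for g, t, s in go_table:
            if s == subtree:
                ann.setdefault(g, set()).add(t)
        freq: dict[str, int] = {}
        for terms in ann.values():
            for t in terms:
                freq[t] = freq.get(t, 0) + 1
        tables[subtree] = (ann, freq)
    return tables


def load_go_tables(
    path: str | Path,
) -> dict[str, tuple[dict[str, set[str]], dict[str, int]]]:
    """Load a ``gene<TAB>term<TAB>subtree`` TSV into per-subtree tables."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        g, t, s = line.split("\t")
        rows.append((g, t, s))
    return _go_tables(rows)


@dataclass
class PipelineOutputs:
    """In-memory results of a run, for scoring against ground truth."""

    run_id: str
    bundle: SimulatedBundle | None = None
    modules: list = field(default_factory=list)
    predictions: list[tuple[str, str, float]] = field(default_factory=list)
    pleiotropy_report: Any = None
    concordance: list = field(default_factory=list)


def discover_modules(
    datasets,
    mosa_config: MOSAConfig,
    edge_budget_fraction: float = 0.05,
    abs_corr: bool = False,
    log: list[str] | None = None,
):
    """Networks + MOSA + filtering for every phenotype with enough datasets."""
    universe = shared_gene_universe(datasets)
    budget = max(1, round(edge_budget_fraction * math.comb(len(universe), 2)))
    nets = [build_network(ds, universe, budget, abs_corr=abs_corr) for ds in datasets]
    by_pheno: dict[str, set[str]] = {}
    for ds in datasets:
        for p in ds.phenotypes:
            by_pheno.setdefault(p, set()).add(ds.id)
    modules = []
    for pheno in sorted(by_pheno):
        ids = by_pheno[pheno]
        if len(ids) < 2 or len(ids) == len(datasets):
            if log is not None:
                log.append(f"{pheno}: skipped (needs >=2 phenotype and >=1 background datasets)")
            continue
        cands = mosa_search(nets, ids, universe, mosa_config, phenotype=pheno)
        kept = filter_modules(cands, mosa_config)
        if log is not None:
            log.append(f"{pheno}: {len(cands)} candidates -> {len(kept)} modules")
        modules.extend(kept)
    return modules, nets, universe


def classify_phenotypes(
    modules,
    annotations: GenePhenotypeDB,
    ontology,
    ppi,
    go_table,
    universe,
    trees: int = 500,
    node_size: int = 10,
    vote_cutoff: float = 0.5,
    seed: int = 0,
    log: list[str] | None = None,
) -> list[tuple[str, str, float]]:
    """Train one classifier per phenotype with modules; return (gene, phenotype, vote)."""
    db = propagate_annotations(annotations, ontology)
    go_tables = _go_tables(go_table)
    out: list[tuple[str, str, float]] = []
    phenos = sorted({m.phenotype for m in modules if m.phenotype})
    for pheno in phenos:
        pheno_modules = [m for m in modules if m.phenotype == pheno]
        union = set().union(*(m.genes for m in pheno_modules))
        G_p = db.known_genes(pheno) & set(universe)
        try:
            split = build_training_split(pheno, union, db, ontology)
        except PhenotypeSkipped as exc:
            if log is not None:
                log.append(str(exc))
            continue
        if not split.negatives:
            if log is not None:
                log.append(f"{pheno}: no negative training genes; skipped")
            continue
        features = []
        for gene in sorted(union):
            mods = [m for m in pheno_modules if gene in m.genes]
            features.append(
                assemble_features(
                    gene, pheno, mods, G_p, set(universe), ppi, go_tables
                )
            )
        try:
            preds, _ = train_and_predict(
                features,
                split,
                n_trees=trees,
                max_node_size=node_size,
                seed=seed,
                vote_cutoff=vote_cutoff,
            )
        except ValueError as exc:
            if log is not None:
                log.append(f"{pheno}: {exc}; skipped")
            continue
        if log is not None:
            log.append(
                f"{pheno}: {len(split.positives)}+/{len(split.negatives)}- "
                f"training genes, {len(preds)} positive predictions"
            )
        out.extend((p.gene, p.phenotype, p.vote_fraction) for p in preds)
    return sorted(out)


def run_pipeline(
    out_dir: str | Path,
    config: Mapping[str, Any] | str | Path | None = None,
    stages: Iterable[str] = STAGES,
    seed: int = 0,
) -> tuple[RunManifest, PipelineOutputs]:
    """Execute the requested stages in dependency order.

    ``config`` may be a mapping or a path to a YAML file with per-stage
    sections (``simulate``, ``network``, ``mosa``, ``classify``, ``chip``).
    Later stages require the in-run outputs of earlier ones; requesting a
    stage without its upstream raises a descriptive error.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = _merge_config(config)
    requested = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for i, s in enumerate(requested):
        if STAGES.index(s) != i:
            raise ValueError(
                f"stage {s!r} requires upstream stage "
                f"{STAGES[STAGES.index(s) - 1]!r} in the same run"
            )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "logs").mkdir(exist_ok=True)
    seeds = {s: stage_seed(seed, s) for s in requested}
    outputs: dict[str, dict[str, str]] = {}
    results = PipelineOutputs(run_id=f"sim-seed{seeds.get('simulate', seed)}")

    bundle = None
    nets = universe = None
    predictions_db = None

    for stage in requested:
        log: list[str] = [f"stage={stage} seed={seeds[stage]}"]
        sdir = _stage_dir(out, stage)

        if stage == "simulate":
            sim_cfg = SimulationConfig(**cfg["simulate"], seed=seeds[stage])
            bundle = simulate_collection(sim_cfg, out_dir=sdir)
            results.bundle = bundle
            results.run_id = bundle.run_id
            outputs[stage] = {
                k: str(Path(v).relative_to(out)) for k, v in bundle.paths.items()
            }
            log.append(f"{len(bundle.datasets)} datasets, {sim_cfg.n_genes} genes")

        elif stage == "discover":
            mosa_cfg = MOSAConfig(**cfg["mosa"], seed=seeds[stage])
            modules, nets, universe = discover_modules(
                bundle.datasets,
                mosa_cfg,
                edge_budget_fraction=cfg["network"]["edge_budget_fraction"],
                abs_corr=cfg["network"]["abs_corr"],
                log=log,
            )
            results.modules = modules
            gmt, stats = sdir / "modules.gmt", sdir / "modules_stats.tsv"
            write_modules(modules, gmt, stats)
            outputs[stage] = {
                "modules_gmt": str(gmt.relative_to(out)),
                "modules_stats": str(stats.relative_to(out)),
            }

        elif stage == "classify":
            preds = classify_phenotypes(
                results.modules,
                bundle.annotations,
                bundle.ontology,
                bundle.ppi,
                bundle.go_table,
                universe,
                trees=cfg["classify"]["trees"],
                node_size=cfg["classify"]["node_size"],
                vote_cutoff=cfg["classify"]["vote_cutoff"],
                seed=seeds[stage],
                log=log,
            )
            results.predictions = preds
            path = sdir / "predictions.tsv"
            lines = ["gene\tphenotype\tvote_fraction"]
            lines += [f"{g}\t{p}\t{v:.6g}" for g, p, v in preds]
            path.write_text("\n".join(lines) + "\n")
            outputs[stage] = {"predictions": str(path.relative_to(out))}
            predictions_db = GenePhenotypeDB(
                {(g, p, "predicted") for g, p, _ in preds}
            )

        elif stage == "pleiotropy":
            known = propagate_annotations(bundle.annotations, bundle.ontology)
            report = pleiotropy_census(
                known,
                bundle.ontology,
                predictions=predictions_db,
                gene_universe=known.genes(),
            )
            results.pleiotropy_report = report
            path = sdir / "pleiotropy.tsv"
            report.to_tsv(path)
            outputs[stage] = {"report": str(path.relative_to(out))}
            log.append(
                f"fraction_pleiotropic={report.fraction_pleiotropic:.4f} "
                f"novel={len(report.novel_pleiotropic)} new_cases={len(report.new_cases)}"
            )

        elif stage == "chip":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                screen = concordance_screen(
                    results.modules,
                    bundle.chips,
                    bundle.ontology,
                    universe,
                    fdr_alpha=cfg["chip"]["fdr_alpha"],
                    pooling=cfg["chip"]["pooling"],
                )
            results.concordance = screen
            path = sdir / "concordance.tsv"
            write_concordance(screen, path)
            outputs[stage] = {"concordance": str(path.relative_to(out))}
            log.append(
                f"{sum(r.significant for r in screen)}/{len(screen)} "
                "phenotypes significant"
            )

        (out / "logs" / f"{stage}.log").write_text("\n".join(log) + "\n")

    hashes = {
        p: _sha256(out / p)
        for stage_outputs in outputs.values()
        for p in stage_outputs.values()
        if (out / p).is_file()
    }
    from phenomod import __version__

    manifest = RunManifest(
        config=cfg,
        master_seed=seed,
        stage_seeds=seeds,
        outputs=outputs,
        hashes=hashes,
        version=__version__,
    )
    manifest.to_json(out / "manifest.json")

    # Convenience scorecard when simulation truth is available.
    if bundle is not None and results.modules:
        card = truth_eval(
            bundle.truth,
            results.run_id,
            modules=results.modules,
            predicted_associations=[(g, p) for g, p, _ in results.predictions],
            called_pleiotropic=(
                set(results.pleiotropy_report.pleiotropic)
                if results.pleiotropy_report is not None
                else None
            ),
            flagged_chip_phenotypes=(
                {r.chip_phenotype for r in results.concordance if r.significant}
                if results.concordance
                else None
            ),
        )
        write_scorecard(card, out / "scorecard.tsv")

    return manifest, results
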