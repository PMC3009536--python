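"""Gene-phenotype association prediction from module membership.

For every gene in a phenotype's modules, five predictor variables are
computed per module and averaged across the modules that contain the gene:

1. module enrichment: -log upper-tail hypergeometric p for the overlap of
   the module with G_p (the genes already known for the phenotype);
2. PPI: the number of protein-protein interactions between the gene and
   module members that are in G_p;
3-5. one GO score per subtree (BP, CC, MF): the sum over distinct GO terms
   the gene shares with its module's G_p members of -log(term background
   frequency / universe size).

Training positives are module genes already annotated with the phenotype;
negatives are module genes with at least one known annotation and none in
the phenotype's related or parental neighborhood; everything else (related/
parental-annotated genes and unannotated genes) is held out for prediction.
A bagged forest of classification trees (500 trees, nodes with <= 10
samples left unsplit, 2 of 5 features per split) scores each gene by the
fraction of trees voting "associated"; training genes are scored out-of-bag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from sklearn.ensemble import RandomForestClassifier

from phenomod.mosa import PhenotypeModule
from phenomod.ontology import GenePhenotypeDB, PhenotypeOntology

FEATURE_NAMES = (
    "enrichment_neglogp",
    "ppi_score",
    "go_bp_score",
    "go_cc_score",
    "go_mf_score",
)

GO_SUBTREES = ("BP", "CC", "MF")


@dataclass
class FeatureVector:
    gene: str
    phenotype: str
    enrichment_neglogp: float
    ppi_score: float
    go_bp_score: float
    go_cc_score: float
    go_mf_score: float
    n_modules: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.enrichment_neglogp,
                self.ppi_score,
                self.go_bp_score,
                self.go_cc_score,
                self.go_mf_score,
            ]
        )


@dataclass
class TrainingSplit:
    positives: set[str]
    negatives: set[str]
    excluded_for_prediction: set[str]

    def __post_init__(self) -> None:
        pairs = [
            (self.positives, self.negatives),
            (self.positives, self.excluded_for_prediction),
            (self.negatives, self.excluded_for_prediction),
        ]
        if any(a & b for a, b in pairs):
            raise ValueError("training split sets must be pairwise disjoint")

    @property
    def all_genes(self) -> set[str]:
        return self.positives | self.negatives | self.excluded_for_prediction


@dataclass
class Prediction:
    gene: str
    phenotype: str
    vote_fraction: float
    label: bool


class PhenotypeSkipped(Exception):
    """Raised when a phenotype has no usable positive training genes."""


def enrichment_feature(
    module_genes: set[str], G_p: set[str], universe: set[str]
) -> float:
    """-log hypergeometric upper-tail p for |module ∩ G_p| or more."""
    if not universe:
        raise ValueError("empty gene universe")
    if not (module_genes <= universe and G_p <= universe):
        raise ValueError("module genes and G_p must lie in the universe")
    overlap = len(module_genes & G_p)
    p = float(
        hypergeom.sf(overlap - 1, len(universe), len(G_p), len(module_genes))
    )
    return -math.log(p) if p > 0 else 745.0


def ppi_feature(
    gene: str,
    module_genes: set[str],
    G_p: set[str],
    ppi: set[tuple[str, str]],
) -> int:
    """Count of PPI edges between ``gene`` and (module ∩ G_p) \\ {gene}."""
    partners = (module_genes & G_p) - {gene}
    norm = {tuple(sorted(e)) for e in ppi}
    return sum(1 for h in partners if tuple(sorted((gene, h))) in norm)


def go_subtree_feature(
    gene: str,
    partners: set[str],
    annotations: Mapping[str, set[str]],
    term_freq: Mapping[str, int],
    universe_size: int,
    go_sig: str = "frequency",
) -> float:
    """GO-sharing score against the module's G_p members for one subtree.

    S is the union over partners of the terms shared with ``gene``; each
    distinct term t contributes -log of its match significance.  With the
    default ``go_sig="frequency"`` the significance is freq(t)/universe_size
    (the chance a random gene carries t); ``go_sig="hypergeom"`` instead uses
    the upper-tail p of observing >= 1 carrier among the partner genes.
    """
    own = annotations.get(gene, set())
    shared: set[str] = set()
    for h in partners - {gene}:
        shared |= own & annotations.get(h, set())
    score = 0.0
    n_partners = len(partners - {gene})
    for t in shared:
        freq = term_freq.get(t, 0)
        if freq <= 0:
            raise ValueError(
                f"GO term {t!r} annotated on genes but has zero background "
                "frequency; annotation table is inconsistent"
            )
        if go_sig == "frequency":
            p = freq / universe_size
        elif go_sig == "hypergeom":
            p = float(hypergeom.sf(0, universe_size, freq, n_partners))
        else:
            raise ValueError(f"unknown go_sig {go_sig!r}")
        score += -math.log(p) if p > 0 else 745.0
    return score


def assemble_features(
    gene: str,
    phenotype: str,
    modules: Sequence[PhenotypeModule],
    G_p: set[str],
    universe: set[str],
    ppi: set[tuple[str, str]],
    go_tables: Mapping[str, tuple[Mapping[str, set[str]], Mapping[str, int]]],
    go_sig: str = "frequency",
) -> FeatureVector:
    """Per-module features, arithmetically averaged across contributing modules.

    ``go_tables`` maps subtree ("BP"/"CC"/"MF") to a pair of
    (gene -> term set, term -> background carrier count).
    """
    if not modules:
        raise ValueError(f"no modules supplied for gene {gene!r}")
    for m in modules:
        if gene not in m.genes:
            raise ValueError(f"gene {gene!r} is not a member of module {m.module_id}")
        if m.phenotype != phenotype:
            raise ValueError("all modules must share the target phenotype")
    rows = []
    for m in modules:
        partners = (m.genes & G_p) - {gene}
        go_scores = []
        for subtree in GO_SUBTREES:
            ann, freq = go_tables.get(subtree, ({}, {}))
            go_scores.append(
                go_subtree_feature(
                    gene, partners, ann, freq, len(universe), go_sig=go_sig
                )
            )
        rows.append(
            [
                enrichment_feature(set(m.genes), G_p, universe),
                float(ppi_feature(gene, set(m.genes), G_p, ppi)),
                *go_scores,
            ]
        )
    mean = np.mean(np.array(rows), axis=0)
    return FeatureVector(
        gene=gene,
        phenotype=phenotype,
        enrichment_neglogp=float(mean[0]),
        ppi_score=float(mean[1]),
        go_bp_score=float(mean[2]),
        go_cc_score=float(mean[3]),
        go_mf_score=float(mean[4]),
        n_modules=len(modules),
    )


def build_training_split(
    phenotype: str,
    module_gene_union: set[str],
    db: GenePhenotypeDB,
    ontology: PhenotypeOntology,
) -> TrainingSplit:
    """Partition a phenotype's module genes into positives/negatives/held-out.

    ``db`` must already be propagated to ancestors.  Raises
    :class:`PhenotypeSkipped` when no module gene is annotated with the
    phenotype (the classifier cannot be trained for it).
    """
    neighborhood = (
        {phenotype}
        | ontology.related_set(phenotype)
        | ontology.parental_set(phenotype)
    )
    positives, negatives, excluded = set(), set(), set()
    for gene in module_gene_union:
        known = db.phenotypes_of(gene, provenance="known")
        if phenotype in known:
            positives.add(gene)
        elif known and not (known & neighborhood):
            negatives.add(gene)
        else:
            excluded.add(gene)
    if not positives:
        raise PhenotypeSkipped(
            f"phenotype {phenotype!r} has no module gene with a known "
            "annotation for it; classifier skipped"
        )
    split = TrainingSplit(positives, negatives, excluded)
    assert split.all_genes == set(module_gene_union)
    return split


def train_and_predict(
    features: Sequence[FeatureVector],
    split: TrainingSplit,
    n_trees: int = 500,
    max_node_size: int = 10,
    seed: int = 0,
    vote_cutoff: float = 0.5,
) -> tuple[list[Prediction], dict[str, float]]:
    """Train the forest and emit vote-fraction-scored predictions.

    Returns the reported predictions (positively predicted training genes
    plus positively predicted held-out genes, at ``vote_cutoff``) and the
    OOB vote fraction per training gene.
    """
    feats = {f.gene: f for f in features}
    train_genes = sorted(split.positives | split.negatives)
    train_genes = [g for g in train_genes if g in feats]
    y = np.array([g in split.positives for g in train_genes])
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    X = np.array([feats[g].as_array() for g in train_genes])

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_split=max_node_size + 1,  # leave nodes of <= max_node_size unsplit
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny training sets can starve OOB
        forest.fit(X, y)
    pos_col = int(np.flatnonzero(forest.classes_ == True)[0])  # noqa: E712
    oob = forest.oob_decision_function_[:, pos_col]
    oob = np.where(np.isnan(oob), 0.5, oob)  # genes never left out get no vote
    oob_scores = {g: float(s) for g, s in zip(train_genes, oob)}

    phenotype = features[0].phenotype if features else ""
    predictions: list[Prediction] = []
    for g, s in oob_scores.items():
        if s >= vote_cutoff:
            predictions.append(Prediction(g, phenotype, s, True))
    held = sorted(g for g in split.excluded_for_prediction if g in feats)
    if held:
        Xh = np.array([feats[g].as_array() for g in held])
        votes = forest.predict_proba(Xh)[:, pos_col]
        for g, s in zip(held, votes):
            if s >= vote_cutoff:
                predictions.append(Prediction(g, phenotype, float(s), True))
    predictions.sort(key=lambda p: (-p.vote_fraction, p.gene))
    return predictions, oob_scores


def precision_recall_curve(
    scores: Mapping[str, float] | Sequence[float],
    labels: Mapping[str, bool] | Sequence[bool],
    cutoffs: Sequence[float] | None = None,
) -> list[tuple[float, float, float]]:
    """(cutoff, precision, recall) across a cutoff grid; score >= cutoff predicts positive.

    Precision with zero predictions is reported as 1.0 (flagged by recall 0).
    """
    if isinstance(scores, Mapping):
        keys = sorted(scores)
        s = np.array([scores[k] for k in keys])
        l = np.array([labels[k] for k in keys], dtype=bool)
    else:
        s = np.asarray(scores, dtype=float)
        l = np.asarray(labels, dtype=bool)
    if s.shape != l.shape:
        raise ValueError("scores and labels must align")
    if cutoffs is None:
        cutoffs = np.linspace(0.0, 1.0, 101)
    n_pos = int(l.sum())
    out = []
    for c in cutoffs:
        pred = s >= c
        tp = int((pred & l).sum())
        fp = int((pred & ~l).sum())
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / n_pos if n_pos else 0.0
        out.append((float(c), precision, recall))
    return out
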