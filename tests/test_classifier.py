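"""Five predictor variables, training-split rules, forest, PR curve."""

import itertools
import math
from math import comb

import numpy as np
import pytest

from phenomod.classifier import (
    FeatureVector,
    PhenotypeSkipped,
    TrainingSplit,
    assemble_features,
    build_training_split,
    enrichment_feature,
    go_subtree_feature,
    ppi_feature,
    precision_recall_curve,
    train_and_predict,
)
from phenomod.mosa import PhenotypeModule
from phenomod.ontology import GenePhenotypeDB, propagate_annotations


def _module(genes, pheno="p1", mid="m1"):
    return PhenotypeModule(
        module_id=mid,
        genes=frozenset(genes),
        phenotype=pheno,
        dense_datasets=frozenset(),
        size=len(genes),
        mean_density=1.0,
        density_differential=0.5,
        specificity_p=0.001,
        fdr_p=0.004,
    )


class TestEnrichmentFeature:
    def test_no_overlap_is_zero(self):
        uni = {f"g{i}" for i in range(10)}
        assert enrichment_feature({"g0", "g1"}, {"g5", "g6"}, uni) == 0.0

    def test_exact_enumeration_value(self):
        uni = {f"g{i}" for i in range(10)}
        module = {"g0", "g1", "g2", "g3"}
        G_p = {"g0", "g1", "g2", "g3", "g4"}
        expected = -math.log(comb(5, 4) / comb(10, 4))
        assert enrichment_feature(module, G_p, uni) == pytest.approx(expected)

    def test_strictly_increasing_with_overlap(self):
        uni = {f"g{i}" for i in range(20)}
        G_p = {f"g{i}" for i in range(8)}
        vals = []
        for k in range(1, 5):
            module = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(10, 14 - k + 10)}
            module = set(list(G_p)[:k]) | {f"g{i}" for i in range(10, 10 + 4 - k)}
            vals.append(enrichment_feature(module, G_p, uni))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_feature(set(), set(), set())


class TestPPIFeature:
    def test_no_edges_zero(self):
        assert ppi_feature("g1", {"g1", "g2"}, {"g2"}, set()) == 0

    def test_counts_only_module_Gp_partners(self):
        ppi = {("g1", "g2"), ("g1", "g3"), ("g1", "g9")}
        assert (
            ppi_feature("g1", {"g1", "g2", "g3", "g4"}, {"g2", "g3", "g4"}, ppi)
            == 2
        )

    def test_matches_edge_count_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(15)]
        for _ in range(20):
            ppi = {
                tuple(sorted(p))
                for p in itertools.combinations(genes, 2)
                if rng.random() < 0.2
            }
            module = set(rng.choice(genes, 6, replace=False))
            G_p = set(rng.choice(genes, 7, replace=False))
            gene = genes[int(rng.integers(15))]
            expected = sum(
                1
                for h in (module & G_p) - {gene}
                if tuple(sorted((gene, h))) in ppi
            )
            assert ppi_feature(gene, module, G_p, ppi) == expected


class TestGoSubtreeFeature:
    def test_no_shared_terms_zero(self):
        ann = {"g1": {"t1"}, "g2": {"t2"}}
        assert go_subtree_feature("g1", {"g2"}, ann, {"t1": 1, "t2": 1}, 100) == 0.0

    def test_rare_term_value(self):
        ann = {"g1": {"t1"}, "g2": {"t1"}}
        score = go_subtree_feature("g1", {"g2"}, ann, {"t1": 1}, 100)
        assert score == pytest.approx(-math.log(0.01))

    def test_term_shared_with_two_partners_counted_once(self):
        ann = {"g1": {"t1"}, "g2": {"t1"}, "g3": {"t1"}}
        one = go_subtree_feature("g1", {"g2"}, ann, {"t1": 3}, 100)
        two = go_subtree_feature("g1", {"g2", "g3"}, ann, {"t1": 3}, 100)
        assert one == pytest.approx(two)

    def test_zero_frequency_term_is_inconsistent(self):
        ann = {"g1": {"t1"}, "g2": {"t1"}}
        with pytest.raises(ValueError, match="frequency"):
            go_subtree_feature("g1", {"g2"}, ann, {}, 100)


class TestAssembleFeatures:
    def go_tables(self):
        return {s: ({}, {}) for s in ("BP", "CC", "MF")}

    def test_single_module_equals_per_module(self):
        uni = {f"g{i}" for i in range(10)}
        m = _module({"g0", "g1", "g2"})
        fv = assemble_features(
            "g0", "p1", [m], {"g1"}, uni, {("g0", "g1")}, self.go_tables()
        )
        assert fv.n_modules == 1
        assert fv.ppi_score == 1.0
        assert fv.enrichment_neglogp == pytest.approx(
            enrichment_feature({"g0", "g1", "g2"}, {"g1"}, uni)
        )

    def test_two_modules_averaged(self):
        uni = {f"g{i}" for i in range(10)}
        m1 = _module({"g0", "g1", "g2"}, mid="m1")
        m2 = _module({"g0", "g3", "g4", "g5"}, mid="m2")
        ppi = {("g0", "g1"), ("g0", "g3"), ("g0", "g4")}
        fv = assemble_features(
            "g0", "p1", [m1, m2], {"g1", "g3", "g4"}, uni, ppi, self.go_tables()
        )
        assert fv.ppi_score == pytest.approx((1 + 2) / 2)
        assert fv.n_modules == 2

    def test_mean_matches_naive_recompute(self):
        rng = np.random.default_rng(1)
        uni = {f"g{i}" for i in range(30)}
        genes = sorted(uni)
        mods = []
        for j in range(5):
            members = set(rng.choice(genes[1:], 6, replace=False)) | {"g0"}
            mods.append(_module(members, mid=f"m{j}"))
        G_p = set(rng.choice(genes, 10, replace=False))
        ppi = {
            tuple(sorted(p))
            for p in itertools.combinations(genes, 2)
            if rng.random() < 0.1
        }
        fv = assemble_features("g0", "p1", mods, G_p, uni, ppi, self.go_tables())
        expected = np.mean(
            [enrichment_feature(set(m.genes), G_p, uni) for m in mods]
        )
        assert fv.enrichment_neglogp == pytest.approx(expected)
        expected_ppi = np.mean(
            [ppi_feature("g0", set(m.genes), G_p, ppi) for m in mods]
        )
        assert fv.ppi_score == pytest.approx(expected_ppi)

    def test_gene_must_belong_to_every_module(self):
        m = _module({"g1", "g2"})
        with pytest.raises(ValueError, match="member"):
            assemble_features(
                "g9", "p1", [m], set(), {"g1", "g2", "g9"}, set(), self.go_tables()
            )


class TestBuildTrainingSplit:
    def db(self, two_branch_ontology, raw):
        return propagate_annotations(
            GenePhenotypeDB(raw), two_branch_ontology
        )

    def test_phenotype_annotated_gene_is_positive(self, two_branch_ontology):
        db = self.db(two_branch_ontology, {("g1", "p1", "known")})
        split = build_training_split("p1", {"g1"}, db, two_branch_ontology)
        assert split.positives == {"g1"}

    def test_related_only_gene_excluded(self, two_branch_ontology):
        # p2 is related to p1; g2 annotated only with p2 (and its ancestors)
        db = self.db(
            two_branch_ontology,
            {("g1", "p1", "known"), ("g2", "p2", "known")},
        )
        split = build_training_split(
            "p1", {"g1", "g2"}, db, two_branch_ontology
        )
        assert "g2" in split.excluded_for_prediction

    def test_disjoint_branch_gene_is_negative(self, two_branch_ontology):
        db = self.db(
            two_branch_ontology,
            {("g1", "p1", "known"), ("g3", "q1", "known")},
        )
        split = build_training_split(
            "p1", {"g1", "g3"}, db, two_branch_ontology
        )
        assert split.negatives == {"g3"}

    def test_unannotated_gene_held_out(self, two_branch_ontology):
        db = self.db(two_branch_ontology, {("g1", "p1", "known")})
        split = build_training_split(
            "p1", {"g1", "g9"}, db, two_branch_ontology
        )
        assert "g9" in split.excluded_for_prediction

    def test_exact_partition(self, two_branch_ontology):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        raw = set()
        for g in genes:
            for p in ("p1", "p2", "q1"):
                if rng.random() < 0.2:
                    raw.add((g, p, "known"))
        raw.add(("g0", "p1", "known"))
        db = propagate_annotations(GenePhenotypeDB(raw), two_branch_ontology)
        union = set(genes)
        split = build_training_split("p1", union, db, two_branch_ontology)
        assert split.all_genes == union
        assert not (split.positives & split.negatives)
        assert not (split.positives & split.excluded_for_prediction)

    def test_no_positives_raises_skip(self, two_branch_ontology):
        db = self.db(two_branch_ontology, {("g3", "q1", "known")})
        with pytest.raises(PhenotypeSkipped):
            build_training_split("p1", {"g3"}, db, two_branch_ontology)


def _feature_table(rng, n_pos, n_neg, shift):
    """Non-negative features; positives shifted upward in all five."""
    feats, labels = [], {}
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        base = np.abs(rng.standard_normal(5)) + (shift if pos else 0.0)
        feats.append(
            FeatureVector(
                gene=f"g{i}",
                phenotype="p1",
                enrichment_neglogp=base[0],
                ppi_score=base[1],
                go_bp_score=base[2],
                go_cc_score=base[3],
                go_mf_score=base[4],
                n_modules=1,
            )
        )
        labels[f"g{i}"] = pos
    return feats, labels


class TestTrainAndPredict:
    def split_for(self, labels):
        pos = {g for g, l in labels.items() if l}
        neg = set(labels) - pos
        return TrainingSplit(pos, neg, set())

    def test_separable_features_high_oob_precision(self):
        rng = np.random.default_rng(3)
        feats, labels = _feature_table(rng, 25, 50, shift=10.0)
        preds, oob = train_and_predict(
            feats, self.split_for(labels), n_trees=200, seed=0
        )
        tp = sum(1 for p in preds if labels[p.gene])
        assert tp / len(preds) >= 0.95

    def test_permuted_labels_near_base_rate(self):
        rng = np.random.default_rng(4)
        feats, labels = _feature_table(rng, 30, 70, shift=0.0)  # no signal
        preds, oob = train_and_predict(
            feats, self.split_for(labels), n_trees=200, seed=0
        )
        scores = np.array([oob[g] for g in sorted(oob)])
        y = np.array([labels[g] for g in sorted(oob)])
        base = y.mean()
        sel = scores >= 0.5
        if sel.sum():
            prec = y[sel].mean()
            sigma = math.sqrt(base * (1 - base) / max(sel.sum(), 1))
            assert abs(prec - base) <= 3 * sigma + 0.05

    def test_same_seed_identical_votes(self):
        rng = np.random.default_rng(5)
        feats, labels = _feature_table(rng, 20, 30, shift=2.0)
        split = self.split_for(labels)
        _, oob1 = train_and_predict(feats, split, n_trees=100, seed=9)
        _, oob2 = train_and_predict(feats, split, n_trees=100, seed=9)
        assert oob1 == oob2

    def test_single_class_errors(self):
        rng = np.random.default_rng(6)
        feats, labels = _feature_table(rng, 10, 0, shift=1.0)
        split = TrainingSplit(set(labels), set(), set())
        with pytest.raises(ValueError, match="both classes"):
            train_and_predict(feats, split)


class TestPrecisionRecallCurve:
    def test_cutoff_zero_full_recall(self):
        pr = precision_recall_curve([0.2, 0.8], [True, False], cutoffs=[0.0])
        assert pr[0][2] == 1.0

    def test_cutoff_above_max_zero_predictions(self):
        pr = precision_recall_curve([0.2, 0.8], [True, False], cutoffs=[0.95])
        assert pr[0][1] == 1.0 and pr[0][2] == 0.0

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(size=10)
        labels = rng.uniform(size=10) < 0.4
        cutoffs = np.linspace(0, 1, 21)
        pr = precision_recall_curve(scores, labels, cutoffs)
        for c, prec, rec in pr:
            pred = scores >= c
            tp = int((pred & labels).sum())
            fp = int((pred & ~labels).sum())
            fn = int((~pred & labels).sum())
            assert prec == pytest.approx(tp / (tp + fp) if tp + fp else 1.0)
            assert rec == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)

    def test_recall_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(size=50)
        labels = rng.uniform(size=50) < 0.5
        pr = precision_recall_curve(scores, labels)
        recalls = [r for _, _, r in pr]
        assert all(b <= a for a, b in zip(recalls, recalls[1:]))
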