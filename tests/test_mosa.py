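"""MOSA search: specificity statistic, energy, filtering, recovery."""

import math
from math import comb

import numpy as np
import pytest

from phenomod.coexpression import CoexpressionNetwork, build_network, shared_gene_universe
from phenomod.mosa import (
    ModuleCandidate,
    MOSAConfig,
    density_differential,
    energy,
    filter_modules,
    mosa_search,
    specificity_pvalue,
)
from phenomod.simulate import SimulationConfig, simulate_collection


class TestSpecificityPvalue:
    def test_zero_overlap_is_one(self):
        assert specificity_pvalue(10, 5, 4, 0) == 1.0

    def test_exact_enumeration_case(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        expected = comb(5, 4) * comb(5, 0) / comb(10, 4)
        assert specificity_pvalue(10, 5, 4, 4) == pytest.approx(expected)

    def test_all_datasets_dense_forces_p_one(self):
        assert specificity_pvalue(10, 5, 10, 5) == pytest.approx(1.0)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            specificity_pvalue(10, 5, 4, 5)

    def test_matches_enumeration_oracle_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            M = int(rng.integers(4, 15))
            K = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            obs = int(rng.integers(0, min(K, N) + 1))
            expected = sum(
                comb(K, k) * comb(M - K, N - k)
                for k in range(obs, min(K, N) + 1)
                if N - k <= M - K
            ) / comb(M, N)
            assert specificity_pvalue(M, K, N, obs) == pytest.approx(expected)


class TestDensityDifferential:
    def tri_net(self, ds_id, full):
        edges = {("a", "b"), ("a", "c"), ("b", "c")} if full else set()
        return CoexpressionNetwork(ds_id, frozenset(edges), frozenset("abc"))

    def test_clique_only_in_phenotype_group(self):
        nets = [self.tri_net("p1", True), self.tri_net("p2", True), self.tri_net("b1", False)]
        assert density_differential(nets, {"a", "b", "c"}, {"p1", "p2"}) == 1.0

    def test_identical_networks_give_zero(self):
        nets = [self.tri_net(i, True) for i in ("p1", "b1", "b2")]
        assert density_differential(nets, {"a", "b", "c"}, {"p1"}) == 0.0

    def test_matches_two_group_mean_oracle(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(8)]
        nets = []
        import itertools

        for d in range(6):
            edges = {
                tuple(sorted(p))
                for p in itertools.combinations(genes, 2)
                if rng.random() < 0.4
            }
            nets.append(CoexpressionNetwork(f"d{d}", frozenset(edges), frozenset(genes)))
        sub = set(genes[:4])
        pheno = {"d0", "d1"}
        from phenomod.coexpression import module_density

        dens = [module_density(n, sub) for n in nets]
        expected = np.mean(dens[:2]) - np.mean(dens[2:])
        assert density_differential(nets, sub, pheno) == pytest.approx(expected)


class TestEnergy:
    def cand(self, objs):
        return ModuleCandidate(
            genes=frozenset("ab"),
            phenotype="p",
            dense_datasets=frozenset(),
            objectives=objs,
            specificity_p=1.0,
            provenance=(0, 0),
        )

    def test_zero_weights_zero_energy(self):
        cfg = MOSAConfig(weights=(0, 0, 0, 0))
        assert energy(self.cand((3.0, 0.5, 0.2, 4.0)), cfg) == 0.0

    def test_weight_linearity(self):
        c = self.cand((1.0, 0.0, 0.0, 0.0))
        e1 = energy(c, MOSAConfig(weights=(1, 0, 0, 0)))
        e2 = energy(c, MOSAConfig(weights=(2, 0, 0, 0)))
        assert e2 == pytest.approx(2 * e1)

    def test_hand_computed_weighted_sum(self):
        c = self.cand((2.0, 0.8, 0.3, 5.0))
        cfg = MOSAConfig(weights=(1.0, 1.0, 1.0, 2.0))
        assert energy(c, cfg) == pytest.approx(-(2.0 + 0.8 + 0.3 + 10.0))


class TestFilterModules:
    def cand(self, genes, density, p, pheno="p"):
        return ModuleCandidate(
            genes=frozenset(genes),
            phenotype=pheno,
            dense_datasets=frozenset({"d1"}),
            objectives=(math.log(len(genes)), density, 0.5, -math.log(p)),
            specificity_p=p,
            provenance=(0, 0),
        )

    def test_size_below_seven_rejected(self):
        c = self.cand([f"g{i}" for i in range(6)], 1.0, 1e-6)
        assert filter_modules([c], MOSAConfig()) == []

    def test_density_below_066_rejected(self):
        c = self.cand([f"g{i}" for i in range(8)], 0.5, 1e-6)
        assert filter_modules([c], MOSAConfig()) == []

    def test_bh_example_by_hand(self):
        # m=4: adjusted = [0.004, 0.004, 0.9, 0.9]; alpha 0.01 keeps two
        genes = [[f"a{i}{j}" for i in range(8)] for j in range(4)]
        cands = [
            self.cand(genes[0], 1.0, 0.001),
            self.cand(genes[1], 1.0, 0.002),
            self.cand(genes[2], 1.0, 0.9),
            self.cand(genes[3], 1.0, 0.9),
        ]
        out = filter_modules(cands, MOSAConfig(fdr_alpha=0.01))
        assert len(out) == 2
        for m in out:
            assert m.fdr_p == pytest.approx(0.004)

    def test_bh_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        cands = [
            self.cand([f"g{j}_{i}" for i in range(8)], 1.0, float(p))
            for j, p in enumerate(rng.uniform(1e-6, 1.0, size=20))
        ]
        out = filter_modules(cands, MOSAConfig(fdr_alpha=0.9))
        for m in out:
            assert m.fdr_p >= m.specificity_p

    def test_exact_duplicates_collapsed(self):
        g = [f"g{i}" for i in range(8)]
        cands = [self.cand(g, 1.0, 1e-5), self.cand(g, 1.0, 1e-4)]
        out = filter_modules(cands, MOSAConfig())
        assert len(out) == 1
        assert out[0].specificity_p == 1e-5

    def test_every_output_passes_all_filters(self):
        rng = np.random.default_rng(3)
        cands = []
        for j in range(30):
            size = int(rng.integers(3, 14))
            cands.append(
                self.cand(
                    [f"g{j}_{i}" for i in range(size)],
                    float(rng.uniform(0.3, 1.0)),
                    float(10 ** rng.uniform(-8, 0)),
                )
            )
        cfg = MOSAConfig()
        for m in filter_modules(cands, cfg):
            assert m.size >= cfg.min_size
            assert m.mean_density >= cfg.min_density
            assert m.fdr_p < cfg.fdr_alpha


def _nets_and_ids(bundle, budget_frac=0.05):
    uni = shared_gene_universe(bundle.datasets)
    budget = round(budget_frac * comb(len(uni), 2))
    nets = [build_network(ds, uni, budget) for ds in bundle.datasets]
    return nets, uni


class TestMosaSearch:
    def test_same_seed_identical_output(self):
        b = simulate_collection(SimulationConfig(seed=11))
        nets, uni = _nets_and_ids(b)
        ids = {ds.id for ds in b.datasets if "PH1" in ds.phenotypes}
        cfg = MOSAConfig(seed=5, restarts=2)
        r1 = mosa_search(nets, ids, uni, cfg, phenotype="PH1")
        r2 = mosa_search(nets, ids, uni, cfg, phenotype="PH1")
        assert [(c.genes, c.objectives, c.specificity_p) for c in r1] == [
            (c.genes, c.objectives, c.specificity_p) for c in r2
        ]

    def test_recovers_planted_clique(self):
        b = simulate_collection(SimulationConfig(seed=12))
        nets, uni = _nets_and_ids(b)
        ids = {ds.id for ds in b.datasets if "PH1" in ds.phenotypes}
        cfg = MOSAConfig(seed=12, restarts=1)
        cands = mosa_search(nets, ids, uni, cfg, phenotype="PH1")
        planted = set(b.truth.module_genes["PH1"])
        best = max(
            len(set(c.genes) & planted) / len(set(c.genes) | planted)
            for c in cands
        )
        assert best >= 0.8

    def test_empty_networks_warn_and_return_nothing(self):
        genes = frozenset(f"g{i}" for i in range(20))
        nets = [
            CoexpressionNetwork(f"d{i}", frozenset(), genes) for i in range(4)
        ]
        with pytest.warns(UserWarning, match="no edges"):
            out = mosa_search(
                nets, {"d0", "d1"}, genes, MOSAConfig(seed=0, restarts=1)
            )
        assert out == []

    def test_needs_two_phenotype_datasets(self):
        genes = frozenset(f"g{i}" for i in range(20))
        nets = [
            CoexpressionNetwork(f"d{i}", frozenset({("g0", "g1")}), genes)
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="phenotype datasets"):
            mosa_search(nets, {"d0"}, genes, MOSAConfig(seed=0))
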