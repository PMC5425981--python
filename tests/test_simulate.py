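"""Synthetic genotypes, architecture phenotypes and gene landscapes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cispred import (
    ArchitectureConfig,
    GenomicRegion,
    scale_to_pve,
    simulate_gene,
    simulate_gene_landscape,
    simulate_genotypes,
)
from cispred.genotypes import empirical_maf


class TestSimulateGenotypes:
    def test_shape_and_maf_floor(self):
        g = simulate_genotypes(200, 80, maf_low=0.05, seed=3)
        assert g.dosages.shape == (200, 80)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        assert g.maf.min() >= 0.04  # generator emulates a post-filter matrix
        assert g.maf.max() <= 0.5
        g.validate_maf()
        assert np.all(np.diff(g.positions) > 0)

    def test_stored_maf_matches_dosages(self, small_genotypes):
        assert np.allclose(
            small_genotypes.maf, empirical_maf(small_genotypes.dosages), atol=1e-12
        )

    def test_determinism(self):
        a = simulate_genotypes(50, 30, seed=11)
        b = simulate_genotypes(50, 30, seed=11)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.positions, b.positions)

    def test_independent_snps_without_ld(self):
        g = simulate_genotypes(465, 150, ld_rho=0.0, seed=2)
        cors = [
            abs(np.corrcoef(g.dosages[:, j], g.dosages[:, j + 1])[0, 1])
            for j in range(g.p - 1)
        ]
        assert np.mean(cors) < 3 / np.sqrt(465)

    def test_ld_increases_adjacent_correlation(self):
        lo = simulate_genotypes(300, 100, ld_rho=0.2, seed=4)
        hi = simulate_genotypes(300, 100, ld_rho=0.9, seed=4)

        def mean_adj(g):
            return np.mean(
                [
                    abs(np.corrcoef(g.dosages[:, j], g.dosages[:, j + 1])[0, 1])
                    for j in range(g.p - 1)
                ]
            )

        assert mean_adj(hi) > mean_adj(lo)

    @pytest.mark.parametrize("bad", [(1, 10), (10, 0)])
    def test_bad_sizes(self, bad):
        with pytest.raises(ValueError):
            simulate_genotypes(*bad)

    def test_bad_maf_bounds(self):
        with pytest.raises(ValueError, match="maf"):
            simulate_genotypes(10, 5, maf_low=0.3, maf_high=0.1)


class TestScaleToPve:
    def test_equal_variances(self, rng):
        g = rng.standard_normal(500)
        g = (g - g.mean()) / g.std()  # population variance exactly 1
        _, sd = scale_to_pve(g, 0.5)
        assert sd == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=30, deadline=None)
    def test_exact_pve(self, target):
        g = np.random.default_rng(1).standard_normal(200) * 2.3
        _, sd = scale_to_pve(g, target)
        assert np.var(g) / (np.var(g) + sd**2) == pytest.approx(target, abs=1e-12)

    def test_noiseless_limit(self, rng):
        g = rng.standard_normal(100)
        _, sd = scale_to_pve(g, 1 - 1e-9)
        assert sd < 1e-3

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            scale_to_pve(np.ones(10), 0.5)


class TestSimulateGene:
    @pytest.mark.parametrize("scenario", ["I", "II", "III"])
    @pytest.mark.parametrize("pve", [0.1, 0.3, 0.5])
    def test_realized_pve_exact(self, small_genotypes, scenario, pve):
        cfg = ArchitectureConfig(scenario, total_pve=pve, n_sparse=5, seed=1)
        gene = simulate_gene(small_genotypes, cfg, 0)
        assert gene.realized_pve == pytest.approx(pve, abs=1e-10)
        # the stored effect vectors must reconstruct the genetic values
        Xc = small_genotypes.dosages - small_genotypes.dosages.mean(axis=0)
        g = Xc @ (gene.beta_polygenic + gene.beta_sparse)
        assert np.var(g) / np.var(gene.expression) == pytest.approx(pve, abs=1e-10)

    def test_scenario_one_component_split(self, small_genotypes):
        cfg = ArchitectureConfig("I", total_pve=0.5, n_sparse=5, seed=2)
        gene = simulate_gene(small_genotypes, cfg, 3)
        poly_share, sparse_share = gene.part_pve
        assert poly_share == pytest.approx(0.30, abs=1e-10)
        assert sparse_share == pytest.approx(0.20, abs=1e-10)

    def test_scenario_three_support(self, small_genotypes):
        cfg = ArchitectureConfig("III", total_pve=0.5, n_sparse=15, seed=4)
        gene = simulate_gene(small_genotypes, cfg, 0)
        assert np.count_nonzero(gene.beta_sparse) == 15
        assert np.count_nonzero(gene.beta_polygenic) == 0
        assert np.array_equal(np.flatnonzero(gene.beta_sparse), gene.sparse_indices)

    def test_scenario_three_ignores_noncausal_columns(self, small_genotypes):
        cfg = ArchitectureConfig("III", total_pve=0.5, n_sparse=5, seed=9)
        gene = simulate_gene(small_genotypes, cfg, 2)
        perturbed = small_genotypes.subset_snps(np.arange(small_genotypes.p))
        noncausal = [j for j in range(perturbed.p) if j not in set(gene.sparse_indices)]
        j = noncausal[0]
        perturbed.dosages[:, j] = np.random.default_rng(0).permutation(
            perturbed.dosages[:, j]
        )
        gene2 = simulate_gene(perturbed, cfg, 2)
        assert np.array_equal(gene.expression, gene2.expression)

    def test_scenario_two_is_dense_polygenic(self, small_genotypes):
        cfg = ArchitectureConfig("II", total_pve=0.3, seed=5)
        gene = simulate_gene(small_genotypes, cfg, 0)
        assert np.count_nonzero(gene.beta_polygenic) == small_genotypes.p
        assert not gene.beta_sparse.any()
        assert gene.sparse_indices.size == 0

    def test_expression_centered(self, small_genotypes):
        cfg = ArchitectureConfig("I", total_pve=0.5, n_sparse=5, seed=6)
        gene = simulate_gene(small_genotypes, cfg, 1)
        assert abs(gene.expression.mean()) < 1e-12

    def test_replicates_reproducible_and_distinct(self, small_genotypes):
        cfg = ArchitectureConfig("II", total_pve=0.5, seed=8)
        a = simulate_gene(small_genotypes, cfg, 0)
        b = simulate_gene(small_genotypes, cfg, 0)
        c = simulate_gene(small_genotypes, cfg, 1)
        assert np.array_equal(a.expression, b.expression)
        assert not np.array_equal(a.expression, c.expression)

    def test_too_many_sparse_snps(self, small_genotypes):
        cfg = ArchitectureConfig("III", total_pve=0.5, n_sparse=small_genotypes.p + 1)
        with pytest.raises(ValueError, match="n_sparse"):
            simulate_gene(small_genotypes, cfg, 0)


class TestArchitectureConfig:
    def test_scenario_two_forces_pure_polygenic(self):
        cfg = ArchitectureConfig("II", total_pve=0.3)
        assert cfg.n_sparse == 0 and cfg.polygenic_share == 1.0
        with pytest.raises(ValueError):
            ArchitectureConfig("II", polygenic_share=0.5)

    def test_scenario_three_forces_pure_sparse(self):
        assert ArchitectureConfig("III").polygenic_share == 0.0
        with pytest.raises(ValueError):
            ArchitectureConfig("III", polygenic_share=0.5)

    @pytest.mark.parametrize("pve", [0.0, 1.0, -0.1])
    def test_pve_bounds(self, pve):
        with pytest.raises(ValueError):
            ArchitectureConfig("I", total_pve=pve)


class TestGeneLandscape:
    CHROMS = {"1": 100_000_000, "2": 80_000_000}

    def _fold(self, genes, region, method="bslmm"):
        from cispred import enrichment_fold, predictive_gene_set

        pred = [g for g in predictive_gene_set(genes, method=method) if g.chrom == region.chrom]
        return enrichment_fold(region, pred, self.CHROMS[region.chrom]).fold

    def test_null_landscape_fold_near_one(self):
        region = GenomicRegion("1", 10_000_001, 30_000_000)
        genes = simulate_gene_landscape(5000, self.CHROMS, region, 1.0, 0.05, seed=1)
        assert 0.6 < self._fold(genes, region) < 1.6

    def test_enriched_landscape_recovers_factor(self):
        # binomial sampling oracle: with the region holding a share rho of the
        # chromosome and predictive rates (f*q inside, q outside), the expected
        # fold is f / ((1 - rho) + f*rho) — the planted factor diluted by the
        # enriched genes' own contribution to the reference set
        factor, rho = 5.0, 0.2
        region = GenomicRegion("1", 10_000_001, 30_000_000)
        expected = factor / ((1 - rho) + factor * rho)
        folds = [
            self._fold(
                genes=simulate_gene_landscape(5000, self.CHROMS, region, factor, 0.05, seed=s),
                region=region,
            )
            for s in range(5)
        ]
        assert np.mean(folds) == pytest.approx(expected, abs=0.35)

    def test_empty_landscape(self):
        assert simulate_gene_landscape(0, self.CHROMS) == []

    def test_region_outside_chromosome(self):
        region = GenomicRegion("1", 1, 200_000_000)
        with pytest.raises(ValueError, match="outside"):
            simulate_gene_landscape(10, self.CHROMS, region, 2.0)

    def test_rate_bound(self):
        with pytest.raises(ValueError):
            simulate_gene_landscape(10, self.CHROMS, None, 30.0, base_rate=0.05)

    def test_r2_respects_predictive_threshold(self):
        genes = simulate_gene_landscape(500, self.CHROMS, seed=2)
        r2 = np.array([g.r2["bslmm"] for g in genes])
        assert ((r2 >= 0.05) | (r2 < 0.05)).all()
        assert r2.min() >= 0.0 and r2.max() <= 0.6
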