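"""Generator checks: pedigree structure, gene dropping, phenotype model."""

import numpy as np
import pytest

from ssgblup.simulate import (SimConfig, SimulationError, simulate_dataset,
                              simulate_genotypes, simulate_pedigree,
                              simulate_phenotypes, _switch_probs)


def small_cfg(**kw):
    base = dict(n_founders=20, n_generations=2, matings_per_generation=8,
                offspring_per_mating=2, n_chromosomes=2, snps_per_chromosome=50,
                prop_phenotyped=(0.2, 0.5), prop_genotyped=0.5, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestPedigreeSim:
    def test_minimal_pedigree(self):
        cfg = small_cfg(n_founders=2, n_generations=1,
                        matings_per_generation=1, offspring_per_mating=1)
        ped = simulate_pedigree(cfg)
        assert ped.n == 3
        assert ped.sire[2] in (0, 1) and ped.dam[2] in (0, 1)
        assert ped.sire[2] != ped.dam[2]

    def test_zero_generations_founders_only(self):
        ped = simulate_pedigree(small_cfg(n_generations=0))
        assert ped.n == 20 and ped.is_founder().all()

    def test_study_scale_animal_count(self):
        # counting oracle: total = founders + generations*matings*offspring
        cfg = SimConfig(seed=2)
        ped = simulate_pedigree(cfg)
        expected = cfg.n_founders + (cfg.n_generations
                                     * cfg.matings_per_generation
                                     * cfg.offspring_per_mating)
        assert ped.n == expected
        assert abs(ped.n - 4129) / 4129 < 0.10

    def test_impossible_mating_demand_raises(self):
        with pytest.raises(SimulationError, match="dams"):
            simulate_pedigree(small_cfg(matings_per_generation=100))

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(small_cfg(n_generations=3))
        idx = np.arange(ped.n)
        assert np.all(ped.sire < idx) and np.all(ped.dam < idx)


class TestGeneDropping:
    def test_fixed_founder_allele_propagates(self):
        # with 2 founders at p=0.5, ~6% of SNPs start fixed for allele 1;
        # every descendant must then carry dosage 2 at those SNPs
        cfg = small_cfg(n_founders=2, n_generations=3,
                        matings_per_generation=1, offspring_per_mating=4,
                        founder_maf_range=(0.5, 0.5),
                        n_chromosomes=2, snps_per_chromosome=200)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        fixed = np.where((geno.dosages[ped.is_founder()] == 2).all(axis=0))[0]
        assert len(fixed) > 0
        assert np.all(geno.dosages[:, fixed] == 2)

    def test_full_sib_dosage_correlation_near_half(self):
        # 200 full-sib pairs from unrelated parents; correlation of centred
        # dosages across sibs estimates the pedigree relationship 0.5
        cfg = SimConfig(n_founders=400, n_generations=1,
                        matings_per_generation=200, offspring_per_mating=2,
                        n_chromosomes=5, snps_per_chromosome=100, seed=5)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        dos = geno.dosages[400:]
        sib1, sib2 = dos[0::2], dos[1::2]
        p = geno.dosages[:400].mean(axis=0) / 2
        keep = (p > 0.05) & (p < 0.95)
        z1 = (sib1 - 2 * p)[:, keep] / np.sqrt(2 * p * (1 - p))[keep]
        z2 = (sib2 - 2 * p)[:, keep] / np.sqrt(2 * p * (1 - p))[keep]
        rel = (z1 * z2).sum(axis=1) / z1.shape[1]
        assert abs(rel.mean() - 0.5) < 0.05

    def test_recombination_rate_matches_haldane_map(self):
        # count phase switches between two adjacent SNPs over many gametes
        import pandas as pd
        from ssgblup.simulate import _gamete

        mm = pd.DataFrame({"snp_id": ["a", "b"], "chrom": [1, 1],
                           "bp": [1, 10_000_001]})  # 10 Mb = 10 cM
        rp = _switch_probs(mm)
        expect = 0.5 * (1 - np.exp(-2 * 0.10))
        rng = np.random.default_rng(0)
        h0 = np.array([0, 0], dtype=np.int8)
        h1 = np.array([1, 1], dtype=np.int8)
        n = 10_000
        switches = sum(int(g[0] != g[1]) for g in
                       (_gamete(h0, h1, rp, rng) for _ in range(n)))
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(switches / n - expect) < 4 * se

    def test_map_strictly_increasing_within_chromosome(self):
        cfg = small_cfg()
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        for _, grp in geno.marker_map.groupby("chrom"):
            assert np.all(np.diff(grp["bp"]) > 0)


class TestPhenotypes:
    def test_zero_heritability_zero_breeding_values(self):
        cfg = small_cfg(trait_h2=(0.0, 0.0))
        ped = simulate_pedigree(cfg)
        phen, truth = simulate_phenotypes(ped, None, cfg)
        assert np.all(truth.true_breeding_values == 0.0)
        v = np.nanvar(phen["trait2"])
        assert v == pytest.approx(cfg.residual_covariance()[1, 1], rel=0.6)

    def test_table_calibration_mean_and_sd(self):
        # 5000 unrelated animals at the reported descriptive statistics
        cfg = SimConfig(n_founders=5000, n_generations=0, n_chromosomes=1,
                        snps_per_chromosome=2, cg_effect_sd=0.0,
                        phenotypic_variance=(0.36 ** 2, 4.09 ** 2),
                        trait_mean=(1.10, 12.49),
                        prop_phenotyped=(1.0, 1.0), seed=7)
        ped = simulate_pedigree(cfg)
        phen, _ = simulate_phenotypes(ped, None, cfg)
        n = 5000
        for col, mu, sd in (("trait1", 1.10, 0.36), ("trait2", 12.49, 4.09)):
            y = phen[col].dropna()
            assert abs(y.mean() - mu) < 3 * sd / np.sqrt(n)
            assert abs(y.std() - sd) < 3 * sd / np.sqrt(2 * n)

    def test_unit_genetic_correlation_degenerate(self):
        cfg = small_cfg(genetic_correlation=1.0, trait_h2=(0.4, 0.4),
                        n_founders=200, n_generations=0)
        ped = simulate_pedigree(cfg)
        _, truth = simulate_phenotypes(ped, None, cfg)
        r = np.corrcoef(truth.true_breeding_values.T)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_trait1_records_nested_in_trait2(self):
        for seed in range(5):
            cfg = small_cfg(seed=seed)
            ped, geno, phen, truth, gids = simulate_dataset(cfg)
            has1 = phen["trait1"].notna()
            has2 = phen["trait2"].notna()
            assert (has1 & ~has2).sum() == 0

    def test_bv_variance_unbiased_across_replicates(self):
        # realized Var(TBV) across 60 replicates is unbiased for sigma2_a
        cfg0 = small_cfg(n_founders=150, n_generations=1,
                         matings_per_generation=60)
        target = np.diag(cfg0.genetic_covariance())
        vars_ = []
        for seed in range(60):
            cfg = small_cfg(n_founders=150, n_generations=1,
                            matings_per_generation=60, seed=seed)
            ped = simulate_pedigree(cfg)
            _, truth = simulate_phenotypes(ped, None, cfg)
            vars_.append(truth.true_breeding_values.var(axis=0, ddof=0))
        vars_ = np.array(vars_)
        mc_se = vars_.std(axis=0, ddof=1) / np.sqrt(len(vars_))
        bias = vars_.mean(axis=0) - target
        assert np.all(np.abs(bias) < 3 * np.maximum(mc_se, 1e-12) + 0.02 * target)

    def test_qtl_mode_matches_target_variance(self):
        cfg = small_cfg(n_qtl=20, n_founders=300, n_generations=0,
                        trait_h2=(0.3, 0.3))
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, geno, cfg)
        realized = truth.true_breeding_values.var(axis=0)
        np.testing.assert_allclose(realized, np.diag(truth.true_G0), rtol=1e-9)
        assert len(truth.qtl_positions) == 20

    def test_invalid_genetic_correlation_rejected(self):
        # |r| <= 1 with valid variances is exactly the PSD condition for a
        # 2x2 covariance, so the guard lives on the correlation bound
        with pytest.raises(SimulationError, match="genetic_correlation"):
            small_cfg(genetic_correlation=1.2)


class TestDeterminism:
    def test_identical_seeds_bit_identical(self):
        a = simulate_dataset(small_cfg(seed=99))
        b = simulate_dataset(small_cfg(seed=99))
        assert a[0].ids == b[0].ids
        np.testing.assert_array_equal(a[1].dosages, b[1].dosages)
        assert a[2].equals(b[2])
        np.testing.assert_array_equal(a[3].true_breeding_values,
                                      b[3].true_breeding_values)
        assert a[4] == b[4]

    def test_different_seeds_differ(self):
        a = simulate_dataset(small_cfg(seed=1))
        b = simulate_dataset(small_cfg(seed=2))
        assert not np.array_equal(a[1].dosages, b[1].dosages)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_cfg(seed=123)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg
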