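"""Genotype QC, allele frequencies, VanRaden G, blending, PLINK round trip."""

import numpy as np
import pandas as pd
import pytest

from ssgblup.genomic import (GenomicsError, GenotypeMatrix, allele_frequencies,
                             blend_G, build_G, center_genotypes,
                             genomic_inbreeding, qc_filter)
from ssgblup.pedigree import RelationshipMatrix
from conftest import hwe_genotypes


def geno_from(dosages, chroms=None, animal_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    mm = pd.DataFrame({
        "snp_id": [f"s{j+1}" for j in range(m)],
        "chrom": chroms if chroms is not None else [1] * m,
        "bp": np.arange(1, m + 1) * 1000,
    })
    return GenotypeMatrix(dosages=dosages, marker_map=mm,
                          animal_ids=animal_ids or [f"a{i+1}" for i in range(n)])


def qc_fixture():
    """10 animals × 12 SNPs, one planted violation per QC criterion.

    s12 non-autosomal; a10 misses 2/11 autosomal SNPs (call rate 0.82);
    s2 misses a9 and a10, so after a10 is removed its call rate is 8/9;
    s3 monomorphic (MAF 0); s4 all heterozygous (HWE deviation 0.5).
    Every other SNP follows Hardy–Weinberg proportions at p = 0.5.
    a9 keeps call rate 10/11 >= 0.9, so it must survive.
    """
    hw = [2, 2, 1, 1, 1, 1, 1, 0, 0, 0]  # HW-ish pattern at p=0.5
    M = np.tile(np.array(hw, dtype=float)[:, None], (1, 12))
    M[:, 2] = 0.0            # s3 monomorphic
    M[:, 3] = 1.0            # s4 all het
    M[8, 1] = np.nan         # a9 misses s2
    M[9, 0] = np.nan         # a10 misses s1
    M[9, 1] = np.nan         # a10 misses s2
    chroms = [1] * 11 + ["X"]
    return geno_from(M, chroms=chroms)


class TestQc:
    def test_planted_violations_removed_exactly(self):
        geno = qc_fixture()
        out, rep = qc_filter(geno)
        assert rep.removed_non_autosomal == 1
        assert rep.removed_animal_call_rate == 1
        assert rep.removed_snp_call_rate == 1
        assert rep.removed_maf == 1
        assert rep.removed_hwe == 1
        assert rep.removed_animal_ids == ["a10"]
        assert rep.removed_snp_ids["non_autosomal"] == ["s12"]
        assert rep.removed_snp_ids["snp_call_rate"] == ["s2"]
        assert rep.removed_snp_ids["maf"] == ["s3"]
        assert rep.removed_snp_ids["hwe"] == ["s4"]
        assert out.n_animals == 9 and out.n_snps == 8
        # accounting identity per dimension
        assert rep.n_snps_in == (rep.n_snps_out + rep.removed_non_autosomal
                                 + rep.removed_snp_call_rate + rep.removed_maf
                                 + rep.removed_hwe)
        assert rep.n_animals_in == rep.n_animals_out + rep.removed_animal_call_rate

    def test_all_heterozygous_snp_fails_hwe(self):
        # p = 0.5, observed het 1.0, |1.0 - 0.5| = 0.5 > 0.15
        M = np.ones((10, 2))
        M[:, 1] = [2, 2, 1, 1, 1, 1, 1, 0, 0, 0]
        out, rep = qc_filter(geno_from(M))
        assert rep.removed_hwe == 1 and out.n_snps == 1

    def test_monomorphic_removed_by_maf(self):
        M = np.column_stack([np.zeros(10), [2, 2, 1, 1, 1, 1, 1, 0, 0, 0]])
        out, rep = qc_filter(geno_from(M))
        assert rep.removed_maf == 1 and out.n_snps == 1

    def test_all_removed_raises_with_report(self):
        with pytest.raises(GenomicsError, match="all SNPs removed"):
            qc_filter(geno_from(np.zeros((10, 3))))


class TestAlleleFrequencies:
    def test_simple_mean(self):
        geno = geno_from([[0.0], [1.0], [2.0]])
        assert allele_frequencies(geno)[0] == pytest.approx(0.5)

    def test_fixed_allele(self):
        geno = geno_from(np.full((4, 1), 2.0))
        assert allele_frequencies(geno)[0] == pytest.approx(1.0)

    def test_matches_naive_loop_with_missing(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 3, size=(20, 30)).astype(float)
        M[rng.random(M.shape) < 0.1] = np.nan
        geno = geno_from(M)
        p = allele_frequencies(geno)
        for j in range(30):
            col = M[:, j]
            expect = np.mean(col[~np.isnan(col)]) / 2
            assert p[j] == pytest.approx(expect)


class TestBuildG:
    def test_single_snp_single_animal(self):
        # p=0.5, dosage 2: z=1, k=0.5, G=2
        geno = geno_from([[2.0]])
        G = build_G(geno, p=np.array([0.5]))
        assert G.values[0, 0] == pytest.approx(2.0)

    def test_zero_centered_gives_zero_G(self):
        geno = geno_from(np.full((3, 4), 1.0))
        G = build_G(geno, p=np.full(4, 0.5))
        np.testing.assert_allclose(G.values, 0.0)

    def test_matches_naive_triple_product(self):
        geno = hwe_genotypes(20, 100, seed=2)
        p = allele_frequencies(geno)
        w = np.random.default_rng(3).uniform(0.5, 2.0, 100)
        G = build_G(geno, p, weights=w)
        Z = geno.dosages - 2 * p
        expect = Z @ np.diag(w) @ Z.T / (2 * np.sum(p * (1 - p)))
        assert np.abs(G.values - expect).max() < 1e-10

    def test_monomorphic_only_raises(self):
        with pytest.raises(GenomicsError, match="zero"):
            build_G(geno_from(np.full((3, 2), 2.0)))

    def test_centering_columns_sum_to_zero(self):
        geno = hwe_genotypes(50, 200, seed=4)
        Z = center_genotypes(geno, allele_frequencies(geno))
        assert np.abs(Z.mean(axis=0)).max() < 1e-10

    def test_mean_diagonal_near_one_under_hwe(self):
        geno = hwe_genotypes(200, 2000, seed=5)
        G = build_G(geno)
        assert abs(np.diag(G.values).mean() - 1.0) < 0.1

    def test_G_positive_semidefinite(self):
        geno = hwe_genotypes(40, 300, seed=6)
        G = build_G(geno)
        assert np.linalg.eigvalsh(G.values).min() > -1e-8

    def test_missing_imputed_to_column_mean(self):
        M = np.array([[0.0, 2], [1, 2], [2, np.nan]])
        geno = geno_from(M)
        p = allele_frequencies(geno)
        Z = center_genotypes(geno, p)
        assert Z[2, 1] == pytest.approx(0.0)  # imputed to 2p then centred


class TestBlending:
    def test_fixed_point_when_G_equals_A22(self):
        vals = np.array([[1.0, 0.3], [0.3, 1.0]])
        G = RelationshipMatrix(vals, ids=["a", "b"], kind="G_raw")
        A22 = RelationshipMatrix(vals, ids=["a", "b"], kind="A22")
        np.testing.assert_allclose(blend_G(G, A22).values, vals)

    def test_full_weight_on_G(self):
        G = RelationshipMatrix(np.eye(2) * 1.2, ids=["a", "b"], kind="G_raw")
        A22 = RelationshipMatrix(np.eye(2), ids=["a", "b"], kind="A22")
        np.testing.assert_allclose(blend_G(G, A22, 1.0, 0.0).values,
                                   np.eye(2) * 1.2)

    def test_blending_restores_invertibility(self):
        # duplicated animal rows make G exactly singular
        geno = hwe_genotypes(10, 50, seed=7)
        M = geno.dosages.copy()
        M[1] = M[0]
        dup = geno_from(M)
        G = build_G(dup)
        assert np.linalg.matrix_rank(G.values) < 10
        A22 = RelationshipMatrix(np.eye(10), ids=dup.animal_ids, kind="A22")
        blended = blend_G(G, A22)  # must not raise: Cholesky succeeds
        np.linalg.cholesky(blended.values)

    def test_id_mismatch_raises(self):
        G = RelationshipMatrix(np.eye(2), ids=["a", "b"], kind="G_raw")
        A22 = RelationshipMatrix(np.eye(2), ids=["b", "a"], kind="A22")
        with pytest.raises(GenomicsError, match="mismatch"):
            blend_G(G, A22)


class TestGenomicInbreeding:
    def test_identity_gives_zero(self):
        G = RelationshipMatrix(np.eye(3), ids=list("abc"), kind="G_raw")
        assert genomic_inbreeding(G) == 0.0

    def test_uniform_excess(self):
        G = RelationshipMatrix(np.eye(3) * 1.25, ids=list("abc"), kind="G_raw")
        assert genomic_inbreeding(G) == pytest.approx(0.25)

    def test_matches_loop(self):
        geno = hwe_genotypes(30, 500, seed=8)
        G = build_G(geno)
        expect = np.mean([G.values[i, i] - 1 for i in range(30)])
        assert genomic_inbreeding(G) == pytest.approx(expect)


class TestPlinkRoundTrip:
    def test_bed_bim_fam_round_trip(self, tmp_path):
        from ssgblup.plinkio import read_plink, write_plink

        rng = np.random.default_rng(9)
        M = rng.integers(0, 3, size=(7, 13)).astype(float)
        M[rng.random(M.shape) < 0.15] = np.nan
        geno = geno_from(M)
        write_plink(geno, tmp_path / "toy")
        back = read_plink(tmp_path / "toy")
        np.testing.assert_array_equal(np.isnan(back.dosages), np.isnan(M))
        np.testing.assert_array_equal(back.dosages[~np.isnan(M)], M[~np.isnan(M)])
        assert back.animal_ids == geno.animal_ids
        assert back.marker_map["bp"].tolist() == geno.marker_map["bp"].tolist()

    def test_tsv_round_trip(self, tmp_path):
        geno = hwe_genotypes(5, 8, seed=10)
        geno.write_tsv(tmp_path / "d.tsv")
        back = GenotypeMatrix.read_tsv(tmp_path / "d.tsv", geno.marker_map)
        np.testing.assert_array_equal(back.dosages, geno.dosages)
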