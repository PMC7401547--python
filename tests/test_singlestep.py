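"""H⁻¹ construction and mixed-model-equation solutions against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ssgblup.genomic import GenotypeMatrix, build_G
from ssgblup.pedigree import build_A, build_Ainv, extract_A22
from ssgblup.singlestep import (ModelError, ModelSpec, build_Hinv, build_mme,
                                solve_mme)
from conftest import random_pedigree


class TestBuildHinv:
    def test_equals_Ainv_when_G_is_A22_and_weights_one(self, ped50):
        Ainv = build_Ainv(ped50)
        gids = list(ped50.ids[20:40])
        A22, A22inv = extract_A22(ped50, gids)
        H = build_Hinv(Ainv, A22inv, A22inv, ped50.positions(gids),
                       tau=1.0, omega=1.0)
        assert np.abs((H - Ainv).toarray()).max() < 1e-12

    def test_no_genotyped_animals_gives_Ainv(self, ped50):
        Ainv = build_Ainv(ped50)
        H = build_Hinv(Ainv, np.empty((0, 0)), np.empty((0, 0)),
                       np.array([], dtype=int))
        assert np.abs((H - Ainv).toarray()).max() == 0.0

    def test_matches_dense_H_inverse(self, ped50):
        # assemble dense H from the joint-distribution identity and invert
        n = ped50.n
        gids = list(ped50.ids[15:35])
        idx = ped50.positions(gids)
        rest = np.setdiff1d(np.arange(n), idx)
        A = build_A(ped50).values
        A22, A22inv = extract_A22(ped50, gids)
        rng = np.random.default_rng(0)
        B = rng.normal(size=(20, 25))
        Gstar = A22.values + B @ B.T / 25 * 0.2
        Hd = A.copy()
        W = A[np.ix_(rest, idx)] @ A22inv
        D = Gstar - A22.values
        Hd[np.ix_(rest, rest)] += W @ D @ W.T
        Hd[np.ix_(rest, idx)] += W @ D
        Hd[np.ix_(idx, rest)] += D @ W.T
        Hd[np.ix_(idx, idx)] += D
        Hinv = build_Hinv(build_Ainv(ped50), np.linalg.inv(Gstar), A22inv,
                          idx, tau=1.0, omega=1.0).toarray()
        assert np.abs(np.linalg.inv(Hd) - Hinv).max() < 1e-6

    def test_misaligned_indices_raise(self, ped50):
        Ainv = build_Ainv(ped50)
        with pytest.raises(ModelError, match="block size"):
            build_Hinv(Ainv, np.eye(3), np.eye(4), np.arange(3))


def founder_geno_setup(n=80, m=500, seed=7):
    """All-genotyped founder population where G is invertible (base allele
    frequencies supplied externally, not re-estimated)."""
    from ssgblup.pedigree import PedigreeTable

    rng = np.random.default_rng(seed)
    ped = PedigreeTable(ids=[f"a{i}" for i in range(n)],
                        sire=np.full(n, -1), dam=np.full(n, -1))
    p0 = rng.uniform(0.1, 0.5, m)
    dos = ((rng.random((n, m)) < p0).astype(float)
           + (rng.random((n, m)) < p0))
    mm = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)], "chrom": 1,
                       "bp": np.arange(1, m + 1) * 1000})
    geno = GenotypeMatrix(dosages=dos, marker_map=mm, animal_ids=list(ped.ids))
    return ped, geno, p0


class TestMmeSolutions:
    G0 = np.array([[0.3, 0.2], [0.2, 0.5]])
    R0 = np.array([[0.7, 0.1], [0.1, 0.5]])

    def test_single_founder_record_is_shrunk_deviation(self):
        from ssgblup.pedigree import PedigreeTable

        ped = PedigreeTable(ids=["x"], sire=np.array([-1]), dam=np.array([-1]))
        phen = pd.DataFrame({"animal": ["x"], "trait1": [np.nan],
                             "trait2": [2.0]})
        spec = ModelSpec(cg_col=None, age_col=None, intercept=False)
        system = build_mme(spec, phen, ped, sparse.identity(1, format="csr"))
        sol = solve_mme(system, np.diag([0.3, 0.4]), np.diag([0.7, 0.6]))
        assert sol.gebv[0, 1] == pytest.approx(2.0 * 0.4 / (0.4 + 0.6))
        assert sol.gebv[0, 0] == pytest.approx(0.0)  # independent traits

    def test_equals_gblup_when_all_genotyped_no_blending(self):
        ped, geno, p0 = founder_geno_setup()
        n = ped.n
        G = build_G(geno, p=p0)
        Ainv = build_Ainv(ped)
        A22, A22inv = extract_A22(ped, list(ped.ids))
        Hinv = build_Hinv(Ainv, np.linalg.inv(G.values), A22inv,
                          ped.positions(ped.ids), tau=1.0, omega=1.0)
        rng = np.random.default_rng(1)
        y = rng.normal(1.0, 1.0, size=(n, 2))
        phen = pd.DataFrame({"animal": ped.ids, "trait1": y[:, 0],
                             "trait2": y[:, 1]})
        spec = ModelSpec(cg_col=None, age_col=None)
        sol = solve_mme(build_mme(spec, phen, ped, Hinv), self.G0, self.R0)
        # independent GBLUP oracle: direct GLS on V = G0 x G + R0 x I
        V = np.kron(self.G0, G.values) + np.kron(self.R0, np.eye(n))
        X = np.kron(np.eye(2), np.ones((n, 1)))
        yv = np.concatenate([y[:, 0], y[:, 1]])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
        ahat = np.kron(self.G0, G.values) @ Vi @ (yv - X @ beta)
        oracle = np.column_stack([ahat[:n], ahat[n:]])
        assert np.abs(sol.gebv - oracle).max() < 1e-8
        np.testing.assert_allclose(sol.fixed_effects["estimate"], beta)

    def test_rebuild_and_resolve_deterministic(self):
        ped = random_pedigree(30, 10, seed=3)
        rng = np.random.default_rng(4)
        phen = pd.DataFrame({
            "animal": ped.ids,
            "trait1": rng.normal(0, 1, 30),
            "trait2": rng.normal(0, 1, 30),
            "cg": rng.choice(["c1", "c2"], 30),
            "age": rng.uniform(12, 18, 30),
        })
        Ainv = build_Ainv(ped)
        spec = ModelSpec()
        base = solve_mme(build_mme(spec, phen, ped, Ainv), self.G0, self.R0)
        again = solve_mme(build_mme(spec, phen, ped, Ainv), self.G0, self.R0)
        np.testing.assert_array_equal(base.gebv, again.gebv)

    def test_zero_genotyped_equals_pedigree_blup(self):
        ped = random_pedigree(60, 12, seed=5)
        rng = np.random.default_rng(6)
        mask = rng.random(60) < 0.6
        phen = pd.DataFrame({
            "animal": np.array(ped.ids)[mask],
            "trait1": rng.normal(0, 1, mask.sum()),
            "trait2": rng.normal(0, 1, mask.sum()),
            "cg": rng.choice(["c1", "c2", "c3"], mask.sum()),
            "age": rng.uniform(12, 18, mask.sum()),
        })
        Ainv = build_Ainv(ped)
        Hinv = build_Hinv(Ainv, np.empty((0, 0)), np.empty((0, 0)),
                          np.array([], dtype=int))
        spec = ModelSpec()
        ss = solve_mme(build_mme(spec, phen, ped, Hinv), self.G0, self.R0)
        ab = solve_mme(build_mme(spec, phen, ped, Ainv), self.G0, self.R0)
        assert np.abs(ss.gebv - ab.gebv).max() < 1e-9

    def test_pcg_path_matches_direct_solve(self):
        ped = random_pedigree(40, 10, seed=8)
        rng = np.random.default_rng(9)
        phen = pd.DataFrame({
            "animal": ped.ids,
            "trait1": rng.normal(0, 1, 40),
            "trait2": rng.normal(0, 1, 40),
            "cg": rng.choice(["c1", "c2"], 40),
            "age": rng.uniform(12, 18, 40),
        })
        system = build_mme(ModelSpec(), phen, ped, build_Ainv(ped))
        direct = solve_mme(system, self.G0, self.R0)
        pcg = solve_mme(system, self.G0, self.R0, dense_threshold=1)
        assert np.abs(direct.gebv - pcg.gebv).max() < 1e-6

    def test_constant_age_covariate_raises(self):
        ped = random_pedigree(10, 5, seed=10)
        phen = pd.DataFrame({
            "animal": ped.ids, "trait1": 1.0, "trait2": 2.0,
            "cg": "c1", "age": 14.0,
        })
        with pytest.raises(ModelError, match="collinear"):
            build_mme(ModelSpec(), phen, ped, build_Ainv(ped))

    def test_empty_cg_levels_warn(self):
        ped = random_pedigree(10, 5, seed=11)
        phen = pd.DataFrame({
            "animal": ped.ids,
            "trait1": [1.0] * 5 + [np.nan] * 5,
            "trait2": np.arange(10, dtype=float),
            "cg": ["c1"] * 5 + ["c2"] * 5,
            "age": np.linspace(12, 18, 10),
        })
        with pytest.warns(UserWarning, match="dropped"):
            build_mme(ModelSpec(), phen, ped, build_Ainv(ped))
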