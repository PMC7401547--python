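"""Single-step mixed-model machinery: H⁻¹ and Henderson's equations.

The single-step evaluation replaces A⁻¹ in the animal-model mixed-model
equations by

    H⁻¹ = A⁻¹ + [0 0; 0  τ·G*⁻¹ − ω·A22⁻¹]

with the correction added into the genotyped block; τ and ω rescale the
genomic and pedigree information (defaults τ = 1.0, ω = 0.7).  The bivariate
model is y = Xβ + Zα + e with fixed contemporary-group effects and a linear
age covariate per trait, α ~ N(0, G0 ⊗ H) in trait-major order, and
per-animal residual covariance restricted to the traits actually observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import cg as sparse_cg

from .pedigree import PedigreeTable


class ModelError(ValueError):
    pass


def build_Hinv(Ainv: sparse.spmatrix, Ginv_blended: np.ndarray,
               A22inv: np.ndarray, genotyped_pos: np.ndarray,
               tau: float = 1.0, omega: float = 0.7) -> sparse.csr_matrix:
    """H⁻¹ = A⁻¹ with τ·G*⁻¹ − ω·A22⁻¹ added into the genotyped block.

    ``genotyped_pos`` gives the pedigree positions (0-based, in the same
    order as the rows of G*⁻¹ and A22⁻¹) of the genotyped animals.
    """
    n = Ainv.shape[0]
    genotyped_pos = np.asarray(genotyped_pos, dtype=np.int64)
    if len(genotyped_pos) != Ginv_blended.shape[0] or len(genotyped_pos) != A22inv.shape[0]:
        raise ModelError("genotyped index count does not match G/A22 block size")
    if len(genotyped_pos) and (genotyped_pos.min() < 0 or genotyped_pos.max() >= n):
        raise ModelError("genotyped positions out of pedigree range")
    Hinv = sparse.lil_matrix(Ainv, copy=True)
    if len(genotyped_pos):
        add = tau * Ginv_blended - omega * A22inv
        Hinv[np.ix_(genotyped_pos, genotyped_pos)] = (
            Hinv[np.ix_(genotyped_pos, genotyped_pos)].toarray() + add)
    return Hinv.tocsr()


@dataclass
class ModelSpec:
    """Bivariate animal model: which phenotype columns carry the traits and
    fixed effects, plus the H⁻¹ scaling factors."""

    trait_cols: tuple = ("trait1", "trait2")
    cg_col: str | None = "cg"
    age_col: str | None = "age"
    intercept: bool = True  # per-trait mean when no CG effect is fitted
    tau: float = 1.0
    omega: float = 0.7


@dataclass
class SolutionSet:
    fixed_effects: pd.DataFrame  # trait, effect, level, estimate
    gebv: np.ndarray  # n_ped x 2, pedigree order
    animal_ids: list
    converged: bool = True
    iterations: int = 0
    final_criterion: float = 0.0

    def gebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal": self.animal_ids,
            "gebv_trait1": self.gebv[:, 0],
            "gebv_trait2": self.gebv[:, 1],
        })

    def write_tsv(self, path) -> None:
        self.gebv_frame().to_csv(path, sep="\t", index=False)


@dataclass
class MixedModelSystem:
    """Assembled design for the bivariate single-step MME.

    Holds everything that does not depend on (G0, R0): sparse design T =
    [X | Z], observation vector y, per-animal observed-trait patterns, and
    H⁻¹.  Coefficient matrix and right-hand side are produced on demand for
    given variance components so REML can re-assemble cheaply.
    """

    T: sparse.csr_matrix  # n_obs x (p + 2 n_ped)
    y: np.ndarray
    p_fixed: int
    n_ped: int
    Hinv: sparse.csr_matrix
    animal_ids: list
    # per observed animal: (pedigree position, observed trait indices, obs row indices)
    patterns: list
    fixed_labels: list  # (trait, effect, level) per fixed column
    logdet_H: float = 0.0

    _T_dense: np.ndarray | None = None
    _pattern_counts: dict | None = None

    @property
    def dim(self) -> int:
        return self.p_fixed + 2 * self.n_ped

    @property
    def T_dense(self) -> np.ndarray:
        """Dense copy of the design (cached); worthwhile at REML scale where
        per-animal sparse row slicing dominates the gradient cost."""
        if self._T_dense is None:
            self._T_dense = self.T.toarray()
        return self._T_dense

    @property
    def pattern_counts(self) -> dict:
        """Number of animals per observed-trait pattern."""
        if self._pattern_counts is None:
            counts: dict = {}
            for _, traits, _ in self.patterns:
                counts[traits] = counts.get(traits, 0) + 1
            self._pattern_counts = counts
        return self._pattern_counts

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def rinv_blocks(self, R0: np.ndarray) -> list:
        out = []
        for _, traits, _ in self.patterns:
            sub = R0[np.ix_(traits, traits)]
            out.append(np.linalg.inv(sub))
        return out

    def rinv_matrix(self, R0: np.ndarray) -> sparse.csr_matrix:
        blocks = self.rinv_blocks(R0)
        rows, cols, vals = [], [], []
        for (_, traits, obs_rows), binv in zip(self.patterns, blocks):
            for a, ra in enumerate(obs_rows):
                for b, rb in enumerate(obs_rows):
                    rows.append(ra)
                    cols.append(rb)
                    vals.append(binv[a, b])
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(self.n_obs, self.n_obs))

    def assemble(self, G0: np.ndarray, R0: np.ndarray):
        """Dense coefficient matrix and RHS for given variance components."""
        Rinv = self.rinv_matrix(R0)
        TtR = self.T.T @ Rinv
        C = (TtR @ self.T).toarray()
        G0inv = np.linalg.inv(G0)
        Ginv_big = sparse.kron(sparse.csr_matrix(G0inv), self.Hinv, format="csr")
        p = self.p_fixed
        C[p:, p:] += Ginv_big.toarray()
        rhs = TtR @ self.y
        return C, rhs, Rinv


def build_mme(spec: ModelSpec, phen: pd.DataFrame, ped: PedigreeTable,
              Hinv: sparse.csr_matrix) -> MixedModelSystem:
    """Assemble the bivariate MME design from a phenotype table.

    ``phen`` has one row per animal: the two trait columns (NaN = missing),
    and the fixed-effect columns named by ``spec``.  Contemporary-group
    levels with no records for a trait are dropped (warning); a constant age
    covariate raises (collinear with the CG dummies).
    """
    t1, t2 = spec.trait_cols
    recs = []  # (ped_pos, trait_idx, value, cg, age)
    for _, row in phen.iterrows():
        pos = ped.positions([row["animal"]])[0]
        for t_idx, col in enumerate((t1, t2)):
            v = row[col]
            if pd.notna(v):
                recs.append((pos, t_idx, float(v),
                             row[spec.cg_col] if spec.cg_col else None,
                             float(row[spec.age_col]) if spec.age_col else 0.0))
    if not recs:
        raise ModelError("no phenotype records")

    # fixed-effect columns per trait
    fixed_labels: list[tuple] = []
    col_of: dict[tuple, int] = {}
    for t_idx in (0, 1):
        t_recs = [r for r in recs if r[1] == t_idx]
        if not t_recs:
            continue
        if spec.cg_col:
            levels = sorted({r[3] for r in t_recs}, key=str)
            all_levels = sorted({str(v) for v in phen[spec.cg_col].dropna()})
            dropped = [lv for lv in all_levels if lv not in {str(x) for x in levels}]
            if dropped:
                warnings.warn(
                    f"trait {t_idx + 1}: contemporary groups without records "
                    f"dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}")
            for lv in levels:
                col_of[(t_idx, "cg", lv)] = len(fixed_labels)
                fixed_labels.append((spec.trait_cols[t_idx], "cg", lv))
        elif spec.intercept:
            col_of[(t_idx, "intercept", "")] = len(fixed_labels)
            fixed_labels.append((spec.trait_cols[t_idx], "intercept", ""))
        if spec.age_col:
            ages = np.array([r[4] for r in t_recs])
            if np.ptp(ages) < 1e-12:
                raise ModelError(
                    f"age covariate is constant for trait {t_idx + 1}: "
                    "collinear with the group effects")
            col_of[(t_idx, "age", "")] = len(fixed_labels)
            fixed_labels.append((spec.trait_cols[t_idx], "age", ""))
    p = len(fixed_labels)
    n = ped.n

    # centre age within trait (keeps the covariate orthogonal to the mean)
    age_mean = {}
    for t_idx in (0, 1):
        ages = [r[4] for r in recs if r[1] == t_idx]
        age_mean[t_idx] = float(np.mean(ages)) if ages else 0.0

    # group observations by animal so residual blocks are contiguous
    recs.sort(key=lambda r: (r[0], r[1]))
    rows, cols, vals = [], [], []
    y = []
    patterns = []
    i = 0
    row_idx = 0
    while i < len(recs):
        pos = recs[i][0]
        j = i
        traits, obs_rows = [], []
        while j < len(recs) and recs[j][0] == pos:
            pos_, t_idx, v, cgv, agev = recs[j]
            y.append(v)
            if spec.cg_col:
                rows.append(row_idx)
                cols.append(col_of[(t_idx, "cg", cgv)])
                vals.append(1.0)
            elif spec.intercept:
                rows.append(row_idx)
                cols.append(col_of[(t_idx, "intercept", "")])
                vals.append(1.0)
            if spec.age_col:
                rows.append(row_idx)
                cols.append(col_of[(t_idx, "age", "")])
                vals.append(agev - age_mean[t_idx])
            rows.append(row_idx)
            cols.append(p + t_idx * n + pos)
            vals.append(1.0)
            traits.append(t_idx)
            obs_rows.append(row_idx)
            row_idx += 1
            j += 1
        patterns.append((pos, tuple(traits), tuple(obs_rows)))
        i = j

    T = sparse.csr_matrix((vals, (rows, cols)), shape=(row_idx, p + 2 * n))
    if Hinv.shape != (n, n):
        raise ModelError("H inverse dimension does not match pedigree size")
    return MixedModelSystem(T=T, y=np.array(y), p_fixed=p, n_ped=n, Hinv=Hinv.tocsr(),
                            animal_ids=list(ped.ids), patterns=patterns,
                            fixed_labels=fixed_labels)


def solve_mme(system: MixedModelSystem, G0: np.ndarray, R0: np.ndarray,
              dense_threshold: int = 12000, tol: float = 1e-10,
              max_iter: int = 20000) -> SolutionSet:
    """Solve the MME: dense Cholesky for small systems, Jacobi-preconditioned
    conjugate gradients above ``dense_threshold`` unknowns."""
    C, rhs, _ = system.assemble(G0, R0)
    if system.dim <= dense_threshold:
        sol = cho_solve(cho_factor(C, lower=True), rhs)
        iters, crit, ok = 0, 0.0, True
    else:
        Cs = sparse.csr_matrix(C)
        d = Cs.diagonal()
        M = sparse.diags(1.0 / np.where(d > 0, d, 1.0))
        sol, info = sparse_cg(Cs, rhs, rtol=tol, maxiter=max_iter, M=M)
        crit = float(np.linalg.norm(Cs @ sol - rhs) / np.linalg.norm(rhs))
        ok = info == 0 and crit < tol
        iters = max_iter if info > 0 else info
        if not ok:
            raise ModelError(
                f"MME conjugate-gradient solve did not converge: "
                f"info={info}, relative residual={crit:.3e}")
    p, n = system.p_fixed, system.n_ped
    fx = pd.DataFrame(system.fixed_labels, columns=["trait", "effect", "level"])
    fx["estimate"] = sol[:p]
    gebv = np.column_stack([sol[p:p + n], sol[p + n:]])
    return SolutionSet(fixed_effects=fx, gebv=gebv, animal_ids=system.animal_ids,
                       converged=ok, iterations=iters, final_criterion=crit)
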