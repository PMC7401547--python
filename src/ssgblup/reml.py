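"""Average-information REML for the bivariate single-step animal model.

Estimates the 2×2 additive-genetic (G0) and residual (R0) covariance
matrices by Newton steps whose Hessian is the average-information matrix

    AI_ij = ½ · y'P (∂V/∂θ_i) P (∂V/∂θ_j) P y,

with exact first derivatives of the REML log-likelihood obtained from the
mixed-model-equation inverse.  Updates are taken on the Cholesky-factor
scale of G0 and R0 (chain rule through the analytic Jacobian), which keeps
both matrices positive semi-definite by construction; step halving enforces
a non-decreasing restricted likelihood.  Standard errors come from the
inverse of the natural-scale AI matrix at convergence, and standard errors
of heritabilities and the genetic correlation by the first-order delta
method.

Missing trait records never enter the equations: each animal's residual
covariance is R0 restricted to its observed traits, so the nested record
structure (one trait measured on a subset of the other's animals) is
handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu

from .singlestep import MixedModelSystem, ModelError

# symmetric parameter basis for a 2x2 covariance: (11), (12), (22)
_E = [np.array([[1.0, 0.0], [0.0, 0.0]]),
      np.array([[0.0, 1.0], [1.0, 0.0]]),
      np.array([[0.0, 0.0], [0.0, 1.0]])]
_IDX = [(0, 0), (0, 1), (1, 1)]


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    """REML estimates with AI-based uncertainty."""

    G0: np.ndarray
    R0: np.ndarray
    se_G0: np.ndarray  # 2x2, elementwise SEs
    se_R0: np.ndarray
    h2: np.ndarray  # per trait
    se_h2: np.ndarray
    r_G: float
    se_r_G: float
    ai_inverse: np.ndarray  # 6x6 covariance of (g11,g12,g22,r11,r12,r22)
    loglik: float = np.nan
    iterations: int = 0
    converged: bool = False
    boundary: bool = False
    trajectory: list = field(default_factory=list)  # -2 logL per accepted step

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), tag in zip(_IDX, ["g11", "g12", "g22"]):
            rows.append((tag, self.G0[i, j], self.se_G0[i, j]))
        for (i, j), tag in zip(_IDX, ["r11", "r12", "r22"]):
            rows.append((tag, self.R0[i, j], self.se_R0[i, j]))
        rows.append(("h2_trait1", self.h2[0], self.se_h2[0]))
        rows.append(("h2_trait2", self.h2[1], self.se_h2[1]))
        rows.append(("r_G", self.r_G, self.se_r_G))
        return pd.DataFrame(rows, columns=["element", "estimate", "se"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _chol_params(M: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(M)
    return np.array([L[0, 0], L[1, 0], L[1, 1]])


def _mat_from_chol(q: np.ndarray) -> np.ndarray:
    L = np.array([[q[0], 0.0], [q[1], q[2]]])
    return L @ L.T


def _jac_chol(q: np.ndarray) -> np.ndarray:
    """d(m11, m12, m22)/d(a, b, c) for M = LL', L = [[a,0],[b,c]]."""
    a, b, c = q
    return np.array([[2 * a, 0.0, 0.0],
                     [b, a, 0.0],
                     [0.0, 2 * b, 2 * c]])


def _tr_sparse_dense(S: sparse.spmatrix, B: np.ndarray) -> float:
    """tr(S @ B) using only the sparse pattern of S."""
    coo = S.tocoo()
    return float(np.sum(coo.data * B[coo.col, coo.row]))


class _RemlWork:
    """Per-iteration quantities for one (G0, R0) evaluation."""

    def __init__(self, sys: MixedModelSystem, G0: np.ndarray, R0: np.ndarray):
        self.sys = sys
        self.G0, self.R0 = G0, R0
        C, rhs, Rinv = sys.assemble(G0, R0)
        self.Rinv = Rinv
        try:
            self.factor = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as e:
            raise RemlError("MME coefficient matrix not positive definite") from e
        self.sol = cho_solve(self.factor, rhs)
        # an ill-conditioned system (e.g. a residual variance collapsing to
        # zero) can factor "successfully" yet solve to garbage, which then
        # masquerades as a huge likelihood gain — verify the solve
        rel_res = (np.linalg.norm(C @ self.sol - rhs)
                   / max(np.linalg.norm(rhs), 1.0))
        if not np.isfinite(rel_res) or rel_res > 1e-6:
            raise RemlError(
                f"mixed-model equations numerically singular "
                f"(relative residual {rel_res:.1e})")
        self.logdet_C = 2.0 * np.sum(np.log(np.diag(self.factor[0])))
        self.ehat = sys.y - sys.T @ self.sol
        self.u = Rinv @ self.ehat  # u = P y
        logdet_R = 0.0
        for traits, count in sys.pattern_counts.items():
            sub = R0[np.ix_(traits, traits)]
            s, ld = np.linalg.slogdet(sub)
            if s <= 0:
                raise RemlError("residual block not positive definite")
            logdet_R += count * ld
        s, ld_g = np.linalg.slogdet(G0)
        if s <= 0:
            raise RemlError("G0 not positive definite")
        self.minus2l = (logdet_R + sys.n_ped * ld_g + sys.logdet_H
                        + self.logdet_C + float(self.y_py(rhs)))

    def y_py(self, rhs) -> float:
        return float(self.sys.y @ self.u)  # y'Rinv(y - T sol) = y'Py

    def gradient_and_ai(self):
        sys = self.sys
        p, n = sys.p_fixed, sys.n_ped
        G0inv = np.linalg.inv(self.G0)
        Cinv = cho_solve(self.factor, np.eye(sys.dim))
        Caa = Cinv[p:, p:]
        ahat = np.stack([self.sol[p:p + n], self.sol[p + n:]])  # 2 x n
        Hi = sys.Hinv
        # cross-products â_t' Hinv â_s and trace blocks tr(Hinv · Caa[s,t])
        Ha = np.stack([Hi @ ahat[0], Hi @ ahat[1]])
        quad_a = ahat @ Ha.T  # 2x2: [t,s] = â_t' Hinv â_s
        tr_blk = np.empty((2, 2))
        for t in range(2):
            for s in range(2):
                tr_blk[t, s] = _tr_sparse_dense(Hi, Caa[s * n:(s + 1) * n, t * n:(t + 1) * n])

        grad_m2l = np.zeros(6)
        for k, E in enumerate(_E):
            M = G0inv @ E @ G0inv
            term1 = n * float(np.sum(G0inv * E))
            term2 = float(np.sum(M * tr_blk))
            quad = float(np.sum(M * quad_a))
            grad_m2l[k] = term1 - term2 - quad

        # residual parameters: per-animal blocks of S = Rinv T Cinv T' Rinv
        T = sys.T
        Td = sys.T_dense
        U = T @ Cinv  # n_obs x dim (dense)
        rinv_blocks = self.sys.rinv_blocks(self.R0)
        for k, E in enumerate(_E):
            term1 = term2 = quad = 0.0
            for (pos, traits, obs_rows), binv in zip(sys.patterns, rinv_blocks):
                Ei = E[np.ix_(traits, traits)]
                if not np.any(Ei):
                    continue
                rows = list(obs_rows)
                TCT = U[rows] @ Td[rows].T  # obs_i x obs_i
                Si = binv @ TCT @ binv
                ui = self.u[rows]
                term1 += float(np.sum(binv * Ei))
                term2 += float(np.sum(Si * Ei.T))
                quad += float(ui @ Ei @ ui)
            grad_m2l[3 + k] = term1 - term2 - quad

        grad_l = -0.5 * grad_m2l

        # AI matrix from working vectors f_i = (dV/dθ_i) P y
        F = np.zeros((sys.n_obs, 6))
        Zs = T[:, p:]
        for k, E in enumerate(_E):
            EG = E @ G0inv
            w = np.concatenate([EG[0, 0] * ahat[0] + EG[0, 1] * ahat[1],
                                EG[1, 0] * ahat[0] + EG[1, 1] * ahat[1]])
            F[:, k] = Zs @ w
        for k, E in enumerate(_E):
            f = np.zeros(sys.n_obs)
            for (pos, traits, obs_rows) in sys.patterns:
                Ei = E[np.ix_(traits, traits)]
                if not np.any(Ei):
                    continue
                rows = list(obs_rows)
                f[rows] = Ei @ self.u[rows]
            F[:, 3 + k] = f
        RinvF = self.Rinv @ F
        Sf = cho_solve(self.factor, T.T @ RinvF)
        PF = self.Rinv @ (F - T @ Sf)
        AI = 0.5 * (F.T @ PF)
        AI = (AI + AI.T) / 2
        return grad_l, AI

    def gebv(self) -> np.ndarray:
        p, n = self.sys.p_fixed, self.sys.n_ped
        return np.column_stack([self.sol[p:p + n], self.sol[p + n:]])


def _start_values(sys: MixedModelSystem) -> tuple[np.ndarray, np.ndarray]:
    """Half the raw phenotypic (co)variance to each of G0 and R0."""
    n = sys.n_ped
    vals = {0: {}, 1: {}}
    for (pos, traits, obs_rows) in sys.patterns:
        for t, r in zip(traits, obs_rows):
            vals[t][pos] = sys.y[r]
    P0 = np.zeros((2, 2))
    for t in (0, 1):
        v = np.array(list(vals[t].values()))
        P0[t, t] = np.var(v, ddof=1) if len(v) > 1 else 1.0
    both = sorted(set(vals[0]) & set(vals[1]))
    if len(both) > 2:
        v0 = np.array([vals[0][i] for i in both])
        v1 = np.array([vals[1][i] for i in both])
        c = np.cov(v0, v1)[0, 1]
        lim = 0.9 * np.sqrt(P0[0, 0] * P0[1, 1])
        P0[0, 1] = P0[1, 0] = np.clip(c, -lim, lim)
    return P0 / 2, P0 / 2



def _fit_once(sys: MixedModelSystem, G0: np.ndarray, R0: np.ndarray,
              max_iter: int, tol: float, verbose: bool) -> dict:
    """One optimisation pass from the given starting matrices."""
    scale = np.sqrt(np.trace(G0) * np.trace(R0)) / 2
    floor = 1e-6 * np.sqrt(scale)
    qg, qr = _chol_params(G0), _chol_params(R0)
    work = _RemlWork(sys, G0, R0)
    trajectory = [work.minus2l]
    converged = False
    stagnant = 0  # consecutive accepted steps with negligible gain
    it = 0
    for it in range(1, max_iter + 1):
        grad_nat, AI = work.gradient_and_ai()
        J = np.zeros((6, 6))
        J[:3, :3] = _jac_chol(qg)
        J[3:, 3:] = _jac_chol(qr)
        grad_L = J.T @ grad_nat
        AI_L = J.T @ AI @ J
        # active set: a Cholesky diagonal heading below its floor is pinned
        # and removed from the system, otherwise its vanishing Jacobian
        # column makes the damped step explode there
        DIAG = (0, 2, 3, 5)
        qcur = np.concatenate([qg, qr])
        free = np.ones(6, dtype=bool)
        delta = np.zeros(6)
        ridge = 1e-8 * max(np.trace(AI_L) / 6.0, 1.0)
        for _ in range(5):
            k = int(free.sum())
            delta[:] = 0.0
            delta[free] = np.linalg.solve(
                AI_L[np.ix_(free, free)] + ridge * np.eye(k), grad_L[free])
            newly = [d for d in DIAG if free[d] and qcur[d] + delta[d] < floor]
            if not newly:
                break
            for d in newly:
                free[d] = False
        for d in DIAG:
            if not free[d]:
                delta[d] = floor - qcur[d]  # land on the floor at full step
        # per-coordinate step cap: a near-singular direction must not swamp
        # the others and degrade the line search into micro-steps
        ref = np.maximum(np.abs(qcur),
                         0.2 * np.repeat([abs(qg[0]) + abs(qg[2]),
                                          abs(qr[0]) + abs(qr[2])], 3))
        cap = 2.0 * ref
        clipped = bool(np.any(np.abs(delta) > cap))
        delta = np.clip(delta, -cap, cap)

        theta_old = np.concatenate([
            [G0[i, j] for i, j in _IDX], [R0[i, j] for i, j in _IDX]])
        step = 1.0
        accepted = None
        for _ in range(10):
            qg_new = qg + step * delta[:3]
            qr_new = qr + step * delta[3:]
            qg_new[[0, 2]] = np.maximum(qg_new[[0, 2]], floor)
            qr_new[[0, 2]] = np.maximum(qr_new[[0, 2]], floor)
            try:
                with np.errstate(all="raise"):
                    G0c, R0c = _mat_from_chol(qg_new), _mat_from_chol(qr_new)
                cand = _RemlWork(sys, G0c, R0c)
                if not np.isfinite(cand.minus2l):
                    raise RemlError("non-finite likelihood")
            except (RemlError, np.linalg.LinAlgError, FloatingPointError):
                step /= 2
                continue
            if cand.minus2l <= work.minus2l + 1e-10:
                accepted = (qg_new, qr_new, cand)
                break
            step /= 2
        if accepted is None:
            # no improving step exists at this precision: treat as converged
            converged = True
            break
        qg, qr, work_new = accepted
        gain = work.minus2l - work_new.minus2l
        work = work_new
        stagnant = stagnant + 1 if gain < 1e-6 * max(abs(work.minus2l), 1.0) else 0
        G0, R0 = work.G0, work.R0
        trajectory.append(work.minus2l)
        if verbose:
            print(f"iter {it}: -2logL = {work.minus2l:.6f} (step {step})")
        theta_new = np.concatenate([
            [G0[i, j] for i, j in _IDX], [R0[i, j] for i, j in _IDX]])
        rel = np.max(np.abs(theta_new - theta_old) /
                     np.maximum(np.abs(theta_old), scale * 1e-3))
        # a clipped or heavily halved step can make the parameter change
        # tiny while the optimum is still far: only a full-length Newton
        # step is evidence of convergence
        if rel < tol and not clipped and step > 0.4:
            converged = True
            break
        if stagnant >= 3:  # boundary creep: likelihood flat
            converged = True
            break

    if not converged:
        err = RemlError(f"AI-REML did not converge in {max_iter} iterations")
        err.trajectory = trajectory
        raise err
    return {"qg": qg, "qr": qr, "work": work, "iterations": it,
            "trajectory": trajectory, "floor": floor}


def ai_reml(sys: MixedModelSystem, start: tuple | None = None,
            max_iter: int = 100, tol: float = 1e-8,
            verbose: bool = False) -> tuple[VarianceComponents, _RemlWork]:
    """Run AI-REML to convergence on a built mixed-model system.

    Returns the variance components and the final solved system state
    (whose ``gebv()`` are the ssGBLUP predictions at the REML estimates).
    Convergence: maximum relative change of the six (co)variance parameters
    below ``tol``.  Raises ``RemlError`` on non-convergence, carrying the
    -2·logL trajectory.  Near-zero variance estimates are flagged as
    boundary, not errors.
    """
    # log|H| is a constant of the fit; compute once for an honest likelihood
    if sys.logdet_H == 0.0:
        lu = splu(sys.Hinv.tocsc())
        sys.logdet_H = -float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    if start is None:
        G0, R0 = _start_values(sys)
    else:
        G0, R0 = (np.asarray(start[0], dtype=float).copy(),
                  np.asarray(start[1], dtype=float).copy())
    for M, name in ((G0, "G0"), (R0, "R0")):
        if np.linalg.eigvalsh(M).min() <= 0:
            raise ModelError(f"starting {name} must be positive definite")

    fit = _fit_once(sys, G0, R0, max_iter=max_iter, tol=tol, verbose=verbose)
    # a fit ending pinned to a correlation boundary (|r| = 1) can stall on
    # the boundary ridge, where the first-order Cholesky-scale curvature is
    # blind; pulling the covariance off the boundary and refitting costs one
    # extra pass and keeps whichever solution has the better likelihood
    for _ in range(2):
        qg, qr, work = fit["qg"], fit["qr"], fit["work"]
        G0c, R0c = work.G0, work.R0
        corrs = []
        var_floor = (10 * fit["floor"]) ** 2
        for M in (G0c, R0c):
            d = np.sqrt(M[0, 0] * M[1, 1])
            # a correlation between two floored variances is an artefact of
            # the zero-variance corner, not a boundary worth refitting
            informative = min(M[0, 0], M[1, 1]) > var_floor
            corrs.append(abs(M[0, 1]) / d if d > 0 and informative else 0.0)
        if max(corrs) < 0.995:
            break
        G0p, R0p = G0c.copy(), R0c.copy()
        if corrs[0] >= 0.995:
            G0p[0, 1] = G0p[1, 0] = 0.85 * G0p[0, 1]
        if corrs[1] >= 0.995:
            R0p[0, 1] = R0p[1, 0] = 0.85 * R0p[0, 1]
        try:
            refit = _fit_once(sys, G0p, R0p, max_iter=min(max_iter, 40),
                              tol=tol, verbose=verbose)
        except RemlError:
            break
        if refit["work"].minus2l < fit["work"].minus2l - 1e-6:
            refit["iterations"] += fit["iterations"]
            fit = refit
        else:
            break

    qg, qr, work = fit["qg"], fit["qr"], fit["work"]
    G0, R0 = work.G0, work.R0
    it = fit["iterations"]
    trajectory = fit["trajectory"]
    converged = True
    floor = fit["floor"]

    _, AI = work.gradient_and_ai()
    ridge = 1e-10 * max(np.trace(AI) / 6.0, 1.0)
    cov = np.linalg.inv(AI + ridge * np.eye(6))
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    se_G0 = np.array([[se[0], se[1]], [se[1], se[2]]])
    se_R0 = np.array([[se[3], se[4]], [se[4], se[5]]])

    g11, g12, g22 = G0[0, 0], G0[0, 1], G0[1, 1]
    r11, r22 = R0[0, 0], R0[1, 1]
    h2 = np.array([g11 / (g11 + r11), g22 / (g22 + r22)])
    # delta method on (g11,g12,g22,r11,r12,r22)
    se_h2 = np.zeros(2)
    for t, (gi, ri, gpos, rpos) in enumerate(((g11, r11, 0, 3), (g22, r22, 2, 5))):
        tot = gi + ri
        grad = np.zeros(6)
        grad[gpos] = ri / tot ** 2
        grad[rpos] = -gi / tot ** 2
        se_h2[t] = np.sqrt(max(grad @ cov @ grad, 0.0))
    denom = np.sqrt(g11 * g22)
    r_G = g12 / denom if denom > 0 else np.nan
    grad = np.zeros(6)
    if denom > 0:
        grad[0] = -0.5 * g12 / (g11 ** 1.5 * np.sqrt(g22))
        grad[1] = 1.0 / denom
        grad[2] = -0.5 * g12 / (g22 ** 1.5 * np.sqrt(g11))
    se_r_G = np.sqrt(max(grad @ cov @ grad, 0.0))

    boundary = bool(min(qg[0], qg[2], qr[0], qr[2]) <= floor * (1 + 1e-9))
    vc = VarianceComponents(
        G0=G0, R0=R0, se_G0=se_G0, se_R0=se_R0, h2=h2, se_h2=se_h2,
        r_G=float(r_G), se_r_G=float(se_r_G), ai_inverse=cov,
        loglik=-0.5 * work.minus2l, iterations=it, converged=converged,
        boundary=boundary, trajectory=trajectory)
    return vc, work
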