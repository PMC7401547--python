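"""Weighted single-step GBLUP GWAS.

SNP effects are obtained by back-solving the genotyped animals' GEBVs,

    û = k⁻¹ · D · Z' · G*⁻¹ · â,

then converted to SNP weights d_i = û_i²·2p_i(1−p_i) (normalised to mean
one), and the evaluation is repeated with the re-weighted genomic matrix —
three iterations by default.  Association signal is summarised as the
percentage of additive genetic variance captured by a moving window of 10
adjacent SNPs (stride one, never crossing a chromosome boundary); windows
above 1% are reported.  The variance denominator is the total genomic
variance Var(Z·û) over genotyped animals, so a single window covering every
SNP accounts for exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import (GenotypeMatrix, allele_frequencies, blend_G, build_G,
                      center_genotypes, vanraden_k)
from .pedigree import RelationshipMatrix
from .singlestep import ModelSpec, build_Hinv, build_mme, solve_mme


class GwasError(ValueError):
    pass


@dataclass
class SnpEffectSet:
    """Back-solved SNP effects for one weighting iteration (both traits)."""

    effects: np.ndarray  # n_snps x 2
    weights: np.ndarray  # n_snps, mean 1
    allele_freq: np.ndarray
    iteration: int
    marker_map: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        df = self.marker_map.copy()
        df["effect_trait1"] = self.effects[:, 0]
        df["effect_trait2"] = self.effects[:, 1]
        df["weight"] = self.weights
        df["iteration"] = self.iteration
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class WindowResult:
    chrom: object
    first_snp: int  # index into the marker map
    last_snp: int
    start_bp: int
    end_bp: int
    pct_variance: float
    trait: str


def backsolve_snp_effects(gebv_genotyped: np.ndarray, Z: np.ndarray,
                          weights: np.ndarray | None, Ginv: np.ndarray,
                          k: float) -> np.ndarray:
    """û = k⁻¹·D·Z′·G⁻¹·â for one or both traits.

    ``gebv_genotyped`` is (n_genotyped,) or (n_genotyped, n_traits); the
    result has matching trailing shape.  When ``Ginv`` is the inverse of the
    unblended Z·D·Z′/k the reconstruction Z·û = â is exact.
    """
    a = np.atleast_2d(np.asarray(gebv_genotyped, dtype=float).T).T
    if a.shape[0] != Z.shape[0]:
        raise GwasError("GEBV length does not match genotyped animal count")
    u = (Z.T @ (Ginv @ a)) / k
    if weights is not None:
        u = u * np.asarray(weights, dtype=float)[:, None]
    if np.ndim(gebv_genotyped) == 1:
        return u[:, 0]
    return u


def update_weights(effects: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Wang-style weights d_i = û_i²·2p_i(1−p_i) for one trait's effects,
    normalised so the mean weight is one (sum = SNP count)."""
    eff = np.asarray(effects, dtype=float)
    if eff.ndim != 1:
        raise GwasError("weights are per trait; pass a single trait's effects")
    raw = eff ** 2 * 2 * p * (1 - p)
    if not np.any(raw > 0):
        raise GwasError("all SNP effects are zero; weights are degenerate")
    return raw / raw.mean()


def window_variances(effects: np.ndarray, Z: np.ndarray,
                     marker_map: pd.DataFrame, window_size: int = 10,
                     total_variance: float | None = None,
                     trait: str = "trait", min_full: bool = True,
                     ) -> list[WindowResult]:
    """Percentage of additive genetic variance per moving SNP window.

    Window variance is the variance over animals of Z_w·û_w; the percentage
    denominator defaults to Var(Z·û) over all SNPs.  Windows slide by one
    SNP within each chromosome; trailing windows shorter than ``window_size``
    are dropped when ``min_full`` (avoids deflated end-of-chromosome spans).
    """
    if window_size < 1:
        raise GwasError("window_size must be >= 1")
    u = np.asarray(effects, dtype=float)
    if total_variance is None:
        total_variance = float(np.var(Z @ u))
    if total_variance <= 0:
        total_variance = np.inf  # all-zero effects -> all windows 0%
    out: list[WindowResult] = []
    mm = marker_map.reset_index(drop=True)
    for chrom, grp in mm.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        n = len(idx)
        last = n - window_size + 1 if min_full else n
        # partial sums of Z_w u_w via a rolling difference keeps this O(n·m)
        bv = np.zeros(Z.shape[0])
        for start in range(max(last, 0)):
            w_idx = idx[start:start + window_size]
            if start == 0:
                bv = Z[:, w_idx] @ u[w_idx]
            else:
                bv = bv - Z[:, idx[start - 1]] * u[idx[start - 1]]
                if start + window_size <= n:
                    j = idx[start + window_size - 1]
                    bv = bv + Z[:, j] * u[j]
            pct = 100.0 * float(np.var(bv)) / total_variance
            out.append(WindowResult(
                chrom=chrom, first_snp=int(w_idx[0]), last_snp=int(w_idx[-1]),
                start_bp=int(mm.loc[w_idx[0], "bp"]), end_bp=int(mm.loc[w_idx[-1], "bp"]),
                pct_variance=pct, trait=trait))
    return out


def windows_frame(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": w.trait, "chrom": w.chrom, "start_bp": w.start_bp,
        "end_bp": w.end_bp, "first_snp": w.first_snp, "last_snp": w.last_snp,
        "pct_variance": w.pct_variance} for w in results])


def report_windows(results: list[WindowResult], threshold_pct: float = 1.0,
                   ) -> pd.DataFrame:
    """Windows above the variance threshold, sorted by percentage within trait."""
    df = windows_frame(results)
    if df.empty:
        return df
    df = df[df["pct_variance"] > threshold_pct]
    return (df.sort_values(["trait", "pct_variance"], ascending=[True, False])
              .reset_index(drop=True))


def run_wssgblup(phen: pd.DataFrame, ped, geno_qc: GenotypeMatrix,
                 A22: RelationshipMatrix, A22inv: np.ndarray,
                 Ainv, G0: np.ndarray, R0: np.ndarray,
                 spec: ModelSpec | None = None, n_iterations: int = 3,
                 focal_trait: int = 0, g_weight: float = 0.95,
                 a_weight: float = 0.05, window_size: int = 10,
                 ) -> tuple[list[SnpEffectSet], list]:
    """Weighted-ssGBLUP GWAS for one trait, variance components held fixed.

    The bivariate evaluation is solved each round, but the SNP weights are
    driven by the focal trait's back-solved effects (the GWAS is run per
    trait, each with its own weighting path).  Iteration 1 uses D = I; each
    later iteration rebuilds G with the updated weights, re-solves the
    evaluation, and re-back-solves effects.  Returns the per-iteration
    effect sets and the final focal-trait window results.
    """
    if spec is None:
        spec = ModelSpec()
    p = allele_frequencies(geno_qc)
    k = vanraden_k(p)
    Z = center_genotypes(geno_qc, p)
    gpos = ped.positions(geno_qc.animal_ids)
    d = np.ones(geno_qc.n_snps)
    sets: list[SnpEffectSet] = []
    for it in range(1, n_iterations + 1):
        G = build_G(geno_qc, p, weights=None if it == 1 else d)
        Gb = blend_G(G, A22, g_weight=g_weight, a_weight=a_weight)
        Ginv = np.linalg.inv(Gb.values)
        Hinv = build_Hinv(Ainv, Ginv, A22inv, gpos, tau=spec.tau, omega=spec.omega)
        system = build_mme(spec, phen, ped, Hinv)
        sol = solve_mme(system, G0, R0)
        a_gen = sol.gebv[gpos, :]
        eff = backsolve_snp_effects(a_gen, Z, d, Ginv, k)
        sets.append(SnpEffectSet(effects=eff, weights=d.copy(), allele_freq=p,
                                 iteration=it, marker_map=geno_qc.marker_map))
        if it < n_iterations:
            d = update_weights(eff[:, focal_trait], p)
    final = sets[-1]
    name = f"trait{focal_trait + 1}"
    windows = window_variances(final.effects[:, focal_trait], Z,
                               geno_qc.marker_map, window_size=window_size,
                               trait=name)
    return sets, windows


def manhattan_plot(windows: list[WindowResult], trait: str, path,
                   threshold_pct: float = 1.0) -> None:
    """Window-variance Manhattan-style plot for one trait."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = windows_frame([w for w in windows if w.trait == trait])
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in df.groupby("chrom", sort=False):
        x = (grp["start_bp"] + grp["end_bp"]) / 2 + offset
        ax.scatter(x, grp["pct_variance"], s=6)
        ticks.append(float(x.mean()))
        labels.append(str(chrom))
        offset += grp["end_bp"].max() + 1
    ax.axhline(threshold_pct, color="grey", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% additive genetic variance")
    ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
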