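"""Synthetic pedigree, genotype and phenotype generator.

Emulates the data structure of a pedigreed beef-cattle population in which
two genetically correlated fertility traits are recorded on partially
overlapping sets of females and a subset of females is genotyped: a
multi-generation pedigree from random mating, gene-dropped SNP genotypes
with Haldane recombination (1 cM ≈ 1 Mb), and bivariate phenotypes built
from contemporary-group effects, a linear age covariate, additive breeding
values and residuals.

Breeding values come in two modes: *infinitesimal* (default), where the
vector of paired trait effects follows N(0, G0 ⊗ A) simulated exactly by
the pedigree gene-flow recursion, and *QTL mode*, where effects at sampled
marker loci are summed and rescaled so the realised genetic (co)variance
matches G0.  Trait-1 records are always a subset of trait-2 records,
mirroring populations where the hormone assay is run only on a nested
subset of the animals scanned for follicle counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .genomic import GenotypeMatrix
from .pedigree import PedigreeTable


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings.  Defaults emulate the study-scale population:
    ~1030 founders plus five generations of ~620 offspring (≈4130 animals),
    29 autosomes, records for the two traits on ~27% / ~7% of animals with
    the trait-1 set nested in the trait-2 set, and ~23% of animals genotyped.
    """

    n_founders: int = 1030
    n_generations: int = 5
    matings_per_generation: int = 310
    offspring_per_mating: int = 2
    n_chromosomes: int = 29
    snps_per_chromosome: int = 70
    chromosome_length_bp: int = 100_000_000
    founder_maf_range: tuple = (0.05, 0.5)
    trait_h2: tuple = (0.28, 0.30)
    genetic_correlation: float = 0.81
    phenotypic_variance: tuple = (0.56, 10.15)
    trait_mean: tuple = (1.10, 12.49)
    n_qtl: int = 0  # 0 = infinitesimal mode
    qtl_big_frac: float = 0.0  # fraction of genetic variance on one major QTL
    n_cg_levels: int = 20
    cg_effect_sd: float = 0.5
    age_slope: tuple = (0.0, 0.0)
    age_range_months: tuple = (12.0, 18.0)
    prop_phenotyped: tuple = (0.07, 0.27)  # (trait1, trait2), trait1 ⊆ trait2
    prop_genotyped: float = 0.23
    seed: int = 1

    def __post_init__(self):
        if not (2 <= len(self.trait_h2) and all(0 <= h <= 1 for h in self.trait_h2)):
            raise SimulationError("trait_h2 must be two values in [0, 1]")
        if not -1 <= self.genetic_correlation <= 1:
            raise SimulationError("genetic_correlation must be in [-1, 1]")
        if self.prop_phenotyped[0] > self.prop_phenotyped[1]:
            raise SimulationError(
                "trait-1 phenotyped proportion cannot exceed trait-2's "
                "(trait-1 records are a nested subset)")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("founder_maf_range must lie in (0, 0.5]")
        g0 = self.genetic_covariance()
        if np.linalg.eigvalsh(g0).min() < -1e-12:
            raise SimulationError(
                f"implied genetic covariance not PSD: h2={self.trait_h2}, "
                f"r_G={self.genetic_correlation}, var_p={self.phenotypic_variance}")

    def genetic_covariance(self) -> np.ndarray:
        """G0 implied by (h², r_G, phenotypic variance)."""
        sa = np.sqrt(np.array(self.trait_h2) * np.array(self.phenotypic_variance))
        g = np.diag(sa ** 2).astype(float)
        g[0, 1] = g[1, 0] = self.genetic_correlation * sa[0] * sa[1]
        return g

    def residual_covariance(self, residual_correlation: float = 0.0) -> np.ndarray:
        se2 = np.array(self.phenotypic_variance) * (1 - np.array(self.trait_h2))
        r = np.diag(se2).astype(float)
        r[0, 1] = r[1, 0] = residual_correlation * np.sqrt(se2[0] * se2[1])
        return r

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise SimulationError("config must set an explicit seed")
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth retained from a simulation for recovery tests."""

    true_breeding_values: np.ndarray  # animals x 2
    qtl_positions: np.ndarray  # marker indices (empty in infinitesimal mode)
    qtl_effects: np.ndarray  # n_qtl x 2
    true_G0: np.ndarray
    true_R0: np.ndarray

    def write_tsv(self, path, animal_ids) -> None:
        df = pd.DataFrame(self.true_breeding_values, columns=["tbv_trait1", "tbv_trait2"])
        df.insert(0, "animal", animal_ids)
        df.to_csv(path, sep="\t", index=False)


def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Random-mating pedigree: founders, then per generation a fixed number
    of sire×dam pairs (drawn from the previous generation, falling back to
    founders) each producing a fixed number of offspring.  Output is
    topologically ordered with founders first; sexes alternate within each
    crop so matings are always feasible downstream.
    """
    if cfg.n_founders < 2:
        raise SimulationError("need at least 2 founders")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    ids = [f"F{i+1}" for i in range(cfg.n_founders)]
    sire = [-1] * cfg.n_founders
    dam = [-1] * cfg.n_founders
    sex = ["M" if i % 2 == 0 else "F" for i in range(cfg.n_founders)]
    prev = list(range(cfg.n_founders))
    for g in range(1, cfg.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if not males or not females:
            raise SimulationError(
                f"generation {g}: no available {'sires' if not males else 'dams'}")
        if cfg.matings_per_generation > len(females):
            raise SimulationError(
                f"generation {g}: {cfg.matings_per_generation} matings requested "
                f"but only {len(females)} dams available (one mating per dam)")
        dams = rng.choice(females, size=cfg.matings_per_generation, replace=False)
        sires = rng.choice(males, size=cfg.matings_per_generation, replace=True)
        crop = []
        k = 0
        for s, d in zip(sires, dams):
            for _ in range(cfg.offspring_per_mating):
                ids.append(f"G{g}_{k+1}")
                sire.append(int(s))
                dam.append(int(d))
                sex.append("M" if k % 2 == 0 else "F")
                crop.append(len(ids) - 1)
                k += 1
        prev = crop
    return PedigreeTable(ids=ids, sire=np.array(sire), dam=np.array(dam),
                         sex=np.array(sex))


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        want = cfg.snps_per_chromosome
        bp = np.unique(rng.integers(1, cfg.chromosome_length_bp, size=2 * want))
        while len(bp) < want:  # collisions are vanishingly rare at bp scale
            extra = rng.integers(1, cfg.chromosome_length_bp, size=2 * want)
            bp = np.unique(np.concatenate([bp, extra]))
        bp = np.sort(rng.choice(bp, size=want, replace=False))
        for j, b in enumerate(bp):
            rows.append((f"snp{c}_{j+1}", c, int(b)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def _switch_probs(mm: pd.DataFrame) -> np.ndarray:
    """Per-SNP phase-switch probabilities for one whole-genome meiosis:
    Haldane r = ½(1 − e^{−2d}) between adjacent SNPs (1 cM per Mb) and ½ at
    each chromosome start, which draws the start phase uniformly (no
    interference, so switches are independent across intervals)."""
    rp = np.empty(len(mm))
    start = 0
    for _, grp in mm.groupby("chrom", sort=False):
        stop = start + len(grp)
        d_morgan = np.diff(grp["bp"].to_numpy()) * 1e-8
        rp[start] = 0.5
        rp[start + 1:stop] = 0.5 * (1 - np.exp(-2 * d_morgan))
        start = stop
    return rp


def _gamete(hap0, hap1, rp, rng) -> np.ndarray:
    """One meiosis across the whole genome in vectorised form."""
    phase = np.cumsum(rng.random(len(rp)) < rp) % 2
    return np.where(phase == 0, hap0, hap1)


def simulate_genotypes(ped: PedigreeTable, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop SNP genotypes through the pedigree.

    Founder haplotype alleles are Bernoulli(p) draws with per-SNP allele
    frequencies uniform on ``founder_maf_range``; offspring receive one
    recombinant gamete from each parent.  Recombination fractions between
    adjacent SNPs follow Haldane's map, r = ½(1 − e^{−2d}) with d in Morgans
    at 1 cM per Mb.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    mm = _marker_map(cfg, rng)
    m = len(mm)
    p = rng.uniform(*cfg.founder_maf_range, size=m)
    rp = _switch_probs(mm)

    n = ped.n
    hapA = np.zeros((n, m), dtype=np.int8)
    hapB = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            hapA[i] = rng.random(m) < p
            hapB[i] = rng.random(m) < p
        else:
            # a parentless side of a single-parent mating draws from the base
            hapA[i] = (_gamete(hapA[s], hapB[s], rp, rng)
                       if s >= 0 else (rng.random(m) < p))
            hapB[i] = (_gamete(hapA[d], hapB[d], rp, rng)
                       if d >= 0 else (rng.random(m) < p))
    dos = (hapA + hapB).astype(float)
    return GenotypeMatrix(dosages=dos, marker_map=mm, animal_ids=list(ped.ids),
                          n_autosomes=cfg.n_chromosomes)


def _infinitesimal_bv(ped: PedigreeTable, G0: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Exact draw from N(0, G0 ⊗ A) by the gene-flow recursion:
    a_i = ½(a_s + a_d) + m_i with Mendelian sampling m_i ~ N(0, d_i·G0)."""
    from .pedigree import compute_inbreeding

    f = compute_inbreeding(ped)
    n = ped.n
    bv = np.zeros((n, 2))
    # Cholesky of G0 once; degenerate (singular) G0 handled via eigendecomp
    w, V = np.linalg.eigh(G0)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (f[s] + f[d])
            mean = 0.5 * (bv[s] + bv[d])
        elif s >= 0 or d >= 0:
            pidx = s if s >= 0 else d
            di = 0.75 - 0.25 * f[pidx]
            mean = 0.5 * bv[pidx]
        else:
            di = 1.0
            mean = 0.0
        bv[i] = mean + np.sqrt(di) * (L @ z[i])
    return bv


def _qtl_bv(ped: PedigreeTable, geno: GenotypeMatrix, cfg: SimConfig,
            G0: np.ndarray, rng: np.random.Generator):
    """Breeding values as sums of marker effects at sampled loci, rescaled so
    the realised per-trait variances match diag(G0) exactly; one optional
    major locus carries ``qtl_big_frac`` of the genetic variance."""
    m = geno.n_snps
    if cfg.n_qtl > m:
        raise SimulationError("n_qtl exceeds SNP count")
    qtl = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    r = cfg.genetic_correlation
    C = np.array([[1.0, r], [r, 1.0]])
    w, V = np.linalg.eigh(C)
    Lc = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    eff = rng.standard_normal((cfg.n_qtl, 2)) @ Lc.T
    if cfg.qtl_big_frac > 0 and cfg.n_qtl > 1:
        # scale the first sampled locus so its variance share ≈ qtl_big_frac
        W = geno.dosages[:, qtl]
        Wc = W - W.mean(axis=0)
        v_site = Wc.var(axis=0) * (eff ** 2).T  # 2 x n_qtl
        rest = v_site[:, 1:].sum(axis=1)
        want = cfg.qtl_big_frac / (1 - cfg.qtl_big_frac) * rest
        have = np.maximum(v_site[:, 0], 1e-12)
        eff[0] *= np.sign(eff[0]) * np.sqrt(want / have)
    W = geno.dosages[:, qtl]
    Wc = W - W.mean(axis=0)
    bv = Wc @ eff
    sd = bv.std(axis=0)
    target = np.sqrt(np.diag(G0))
    scale = np.where(sd > 0, target / np.maximum(sd, 1e-12), 0.0)
    bv *= scale
    eff *= scale
    return bv, qtl, eff


def simulate_phenotypes(ped: PedigreeTable, geno: GenotypeMatrix | None,
                        cfg: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Bivariate phenotypes under the additive model the evaluation fits.

    phenotype = trait mean + CG effect + age_slope·(age − mean age)
                + breeding value + residual.
    Missingness: the trait-2 record set is sampled from females (falling
    back to all animals when females are too few), and the trait-1 set is a
    nested subsample of it.  Returns a phenotype frame (one row per animal
    with NaN for unrecorded traits) and the simulation truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 37]))
    G0 = cfg.genetic_covariance()
    R0 = cfg.residual_covariance()
    n = ped.n

    if cfg.n_qtl > 0:
        if geno is None:
            raise SimulationError("QTL mode requires genotypes")
        bv, qtl, eff = _qtl_bv(ped, geno, cfg, G0, rng)
    else:
        bv = (_infinitesimal_bv(ped, G0, rng)
              if np.any(np.diag(G0) > 0) else np.zeros((n, 2)))
        qtl = np.array([], dtype=int)
        eff = np.zeros((0, 2))

    we, Ve = np.linalg.eigh(R0)
    Le = Ve @ np.diag(np.sqrt(np.clip(we, 0, None)))
    resid = rng.standard_normal((n, 2)) @ Le.T

    cg = rng.integers(0, cfg.n_cg_levels, size=n)
    cg_eff = rng.normal(0.0, cfg.cg_effect_sd, size=(cfg.n_cg_levels, 2))
    age = rng.uniform(*cfg.age_range_months, size=n)
    age_c = age - age.mean()

    y = (np.asarray(cfg.trait_mean)[None, :] + cg_eff[cg]
         + age_c[:, None] * np.asarray(cfg.age_slope)[None, :]
         + bv + resid)

    # record sets: trait 2 from females, trait 1 nested inside trait 2
    females = np.where(ped.sex == "F")[0] if ped.sex is not None else np.arange(n)
    n2 = min(int(round(cfg.prop_phenotyped[1] * n)), n)
    pool = females if len(females) >= n2 else np.arange(n)
    set2 = rng.choice(pool, size=n2, replace=False)
    n1 = min(int(round(cfg.prop_phenotyped[0] * n)), n2)
    set1 = rng.choice(set2, size=n1, replace=False)
    obs = np.full((n, 2), np.nan)
    obs[set2, 1] = y[set2, 1]
    obs[set1, 0] = y[set1, 0]

    phen = pd.DataFrame({
        "animal": ped.ids,
        "trait1": obs[:, 0],
        "trait2": obs[:, 1],
        "cg": [f"cg{c+1}" for c in cg],
        "age": age,
    })
    truth = TruthRecord(true_breeding_values=bv, qtl_positions=qtl,
                        qtl_effects=eff, true_G0=G0, true_R0=R0)
    return phen, truth


def select_genotyped(ped: PedigreeTable, phen: pd.DataFrame, cfg: SimConfig,
                     ) -> list:
    """Choose the genotyped subset: phenotyped females first (as in a
    female-fertility genotyping scheme), topped up with other females,
    then any animal."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 53]))
    n_g = int(round(cfg.prop_genotyped * ped.n))
    recorded = phen.loc[phen["trait2"].notna(), "animal"].tolist()
    rec_idx = list(ped.positions(recorded))
    females = (set(np.where(ped.sex == "F")[0].tolist())
               if ped.sex is not None else set(range(ped.n)))
    tier1 = [i for i in rec_idx if i in females]
    tier2 = sorted(females - set(tier1))
    tier3 = [i for i in range(ped.n) if i not in females and i not in set(tier1)]
    chosen: list[int] = []
    for tier in (tier1, tier2, tier3):
        need = n_g - len(chosen)
        if need <= 0:
            break
        tier = np.asarray(tier)
        take = tier if len(tier) <= need else rng.choice(tier, size=need, replace=False)
        chosen.extend(int(i) for i in take)
    chosen = sorted(chosen[:n_g])
    return [ped.ids[i] for i in chosen]


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: pedigree + genotypes + phenotypes + genotyped ids."""
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, geno, cfg)
    gids = select_genotyped(ped, phen, cfg)
    return ped, geno, phen, truth, gids
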