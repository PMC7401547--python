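"""Reference simulation studies used for package validation.

Each function runs one self-contained study at a fixed design and returns
plain numbers, so the same code backs both the test suite and the
reproduction script:

* :func:`recovery_replicate` — simulate a population at the reported
  genetic-parameter values (bivariate h² = 0.28 / 0.30, r_G = 0.81) with
  the study's data structure (five generations, nested trait-1 records,
  ~40% of animals genotyped) and re-estimate the parameters by single-step
  AI-REML.  The design is scaled to 1500 pedigree animals / 2000 SNPs so a
  replicate fits in well under a minute.
* :func:`qtl_detection_replicate` — plant one major QTL carrying 30% of
  the genetic variance and ask whether the top >1% window of a three-
  iteration weighted-ssGBLUP GWAS lands on it.
* :func:`calibration_sample` — draw phenotypes at the reported descriptive
  statistics (means 1.10 / 12.49, SDs 0.36 / 4.09) for a large unrelated
  sample.
"""

from __future__ import annotations

import numpy as np

from .genomic import allele_frequencies, blend_G, build_G, qc_filter
from .gwas import report_windows, run_wssgblup
from .pedigree import build_Ainv, compute_inbreeding, extract_A22
from .reml import VarianceComponents, ai_reml
from .simulate import SimConfig, simulate_dataset, simulate_pedigree, simulate_phenotypes
from .singlestep import ModelSpec, build_Hinv, build_mme

#: generator settings shared by the recovery replicates: study-shaped
#: population scaled to 1500 animals with ~600 genotyped females
RECOVERY_SIM = dict(
    n_founders=250, n_generations=5, matings_per_generation=125,
    offspring_per_mating=2, n_chromosomes=10, snps_per_chromosome=200,
    trait_h2=(0.28, 0.30), genetic_correlation=0.81,
    phenotypic_variance=(0.56, 10.15), trait_mean=(1.10, 12.49),
    prop_phenotyped=(0.25, 0.70), prop_genotyped=0.40,
    cg_effect_sd=0.5, age_slope=(0.01, 0.1),
)

#: single planted 30%-of-variance QTL among a polygenic background
QTL_SIM = dict(
    n_founders=200, n_generations=4, matings_per_generation=100,
    offspring_per_mating=2, n_chromosomes=5, snps_per_chromosome=200,
    n_qtl=50, qtl_big_frac=0.30, trait_h2=(0.30, 0.30),
    genetic_correlation=0.80, phenotypic_variance=(1.0, 1.0),
    trait_mean=(0.0, 0.0), prop_phenotyped=(0.5, 0.9), prop_genotyped=0.60,
    cg_effect_sd=0.3,
)


def single_step_system(ped, phen, geno_qc, tau=1.0, omega=0.7):
    """Assemble H⁻¹ and the bivariate MME for a QC'd dataset."""
    f = compute_inbreeding(ped)
    Ainv = build_Ainv(ped, f)
    A22, A22inv = extract_A22(ped, geno_qc.animal_ids)
    G = build_G(geno_qc, allele_frequencies(geno_qc))
    Gb = blend_G(G, A22)
    Ginv = np.linalg.inv(Gb.values)
    gpos = ped.positions(geno_qc.animal_ids)
    Hinv = build_Hinv(Ainv, Ginv, A22inv, gpos, tau=tau, omega=omega)
    spec = ModelSpec(tau=tau, omega=omega)
    return build_mme(spec, phen, ped, Hinv), (Ainv, A22, A22inv)


def recovery_replicate(seed: int, reml_tol: float = 1e-6) -> VarianceComponents:
    """One parameter-recovery replicate: simulate, QC, fit AI-REML."""
    cfg = SimConfig(seed=seed, **RECOVERY_SIM)
    ped, geno, phen, truth, gids = simulate_dataset(cfg)
    geno_g = geno.subset(animal_idx=list(ped.positions(gids)))
    geno_qc, _ = qc_filter(geno_g)
    system, _ = single_step_system(ped, phen, geno_qc)
    vc, _ = ai_reml(system, tol=reml_tol)
    return vc

def recovery_study(seeds) -> dict:
    """Mean AI-REML estimates across replicates (the headline recovery)."""
    h2 = []
    rg = []
    for s in seeds:
        vc = recovery_replicate(s)
        h2.append(vc.h2)
        rg.append(vc.r_G)
    h2 = np.array(h2)
    return {
        "h2_trait1_mean": float(h2[:, 0].mean()),
        "h2_trait2_mean": float(h2[:, 1].mean()),
        "r_G_mean": float(np.mean(rg)),
        "h2_per_replicate": h2.tolist(),
        "r_G_per_replicate": [float(x) for x in rg],
        "truth": {"h2": list(RECOVERY_SIM["trait_h2"]),
                  "r_G": RECOVERY_SIM["genetic_correlation"]},
    }


def qtl_detection_replicate(seed: int, focal_trait: int = 1) -> bool:
    """True when the top >1% window of the weighted GWAS overlaps the
    planted major QTL (variance components held at the generating truth)."""
    cfg = SimConfig(seed=seed, **QTL_SIM)
    ped, geno, phen, truth, gids = simulate_dataset(cfg)
    geno_g = geno.subset(animal_idx=list(ped.positions(gids)))
    geno_qc, _ = qc_filter(geno_g)
    f = compute_inbreeding(ped)
    Ainv = build_Ainv(ped, f)
    A22, A22inv = extract_A22(ped, geno_qc.animal_ids)
    sets, windows = run_wssgblup(
        phen, ped, geno_qc, A22, A22inv, Ainv, truth.true_G0, truth.true_R0,
        n_iterations=3, focal_trait=focal_trait)
    top = report_windows(windows, threshold_pct=1.0)
    if top.empty:
        return False
    qtl_idx = truth.qtl_positions[0]
    qtl_chrom = geno.marker_map.loc[qtl_idx, "chrom"]
    qtl_bp = int(geno.marker_map.loc[qtl_idx, "bp"])
    w = top.iloc[0]
    return bool(w["chrom"] == qtl_chrom
                and w["start_bp"] <= qtl_bp <= w["end_bp"])


def calibration_sample(seed: int, n: int = 5000):
    """Phenotypes for n unrelated animals at the reported descriptive
    statistics; returns the phenotype frame."""
    cfg = SimConfig(
        n_founders=n, n_generations=0, n_chromosomes=1, snps_per_chromosome=2,
        trait_h2=(0.28, 0.30), genetic_correlation=0.81,
        phenotypic_variance=(0.36 ** 2, 4.09 ** 2), trait_mean=(1.10, 12.49),
        cg_effect_sd=0.0, prop_phenotyped=(1.0, 1.0), seed=seed)
    ped = simulate_pedigree(cfg)
    phen, _ = simulate_phenotypes(ped, None, cfg)
    return phen
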