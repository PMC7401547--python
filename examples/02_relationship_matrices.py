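"""Pedigree and genomic relationship matrices and the single-step H⁻¹.

Shows the building blocks of a single-step evaluation: the numerator
relationship matrix A (with inbreeding), the VanRaden genomic matrix
G = ZZ′/k for the genotyped subset, the 0.95·G + 0.05·A22 blend that keeps
G invertible, and the combined H⁻¹ with τ = 1.0, ω = 0.7.
"""

import numpy as np

from ssgblup import (SimConfig, simulate_dataset, compute_inbreeding,
                     build_Ainv, extract_A22, allele_frequencies, build_G,
                     blend_G, genomic_inbreeding, build_Hinv, qc_filter)

cfg = SimConfig(n_founders=100, n_generations=4, matings_per_generation=50,
                offspring_per_mating=2, n_chromosomes=5,
                snps_per_chromosome=200, prop_genotyped=0.5, seed=3)
ped, geno, phen, truth, gids = simulate_dataset(cfg)
geno = geno.subset(animal_idx=list(ped.positions(gids)))
geno, report = qc_filter(geno)
print(report.to_frame().to_string(index=False))

f = compute_inbreeding(ped)
Ainv = build_Ainv(ped, f)
A22, A22inv = extract_A22(ped, geno.animal_ids)
G = build_G(geno, allele_frequencies(geno))
Gb = blend_G(G, A22)

print(f"\nmean pedigree inbreeding F: {f.mean():.4f}")
print(f"mean genomic inbreeding (diag G - 1): {genomic_inbreeding(G):.4f}")
print(f"mean diag(G) = {np.diag(G.values).mean():.3f} "
      "(close to 1 under the VanRaden scaling)")

Hinv = build_Hinv(Ainv, np.linalg.inv(Gb.values), A22inv,
                  ped.positions(geno.animal_ids), tau=1.0, omega=0.7)
print(f"H-inverse: {Hinv.shape[0]}x{Hinv.shape[1]}, "
      f"{Hinv.nnz} non-zeros ({100 * Hinv.nnz / Hinv.shape[0] ** 2:.1f}% dense)")
# A⁻¹ is sparse (Henderson's rules touch only parent-offspring triplets);
# the genomic correction fills in the genotyped block only.
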