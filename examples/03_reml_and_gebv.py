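"""Bivariate AI-REML variance components and ssGBLUP breeding values.

Fits the two-trait animal model y = Xβ + Zα + e with contemporary-group
and age fixed effects and α ~ N(0, G0 ⊗ H), estimates G0 and R0 by
average-information REML, and prints heritabilities, the genetic
correlation (with standard errors) and the accuracy of the resulting
genomic breeding values against the simulation truth.
"""

import numpy as np

from ssgblup import SimConfig, simulate_dataset, qc_filter, ai_reml
from ssgblup.study import single_step_system

cfg = SimConfig(n_founders=150, n_generations=4, matings_per_generation=75,
                offspring_per_mating=2, n_chromosomes=5,
                snps_per_chromosome=200, trait_h2=(0.28, 0.30),
                genetic_correlation=0.81, prop_phenotyped=(0.35, 0.8),
                prop_genotyped=0.5, seed=42)
ped, geno, phen, truth, gids = simulate_dataset(cfg)
geno_qc, _ = qc_filter(geno.subset(animal_idx=list(ped.positions(gids))))
system, _ = single_step_system(ped, phen, geno_qc)

vc, fit = ai_reml(system)
print(vc.to_frame().to_string(index=False))
print(f"\nconverged in {vc.iterations} AI iterations; "
      f"log-likelihood {vc.loglik:.2f}")
print(f"true h2: {cfg.trait_h2}, true r_G: {cfg.genetic_correlation}")

gebv = fit.gebv()
for t in (0, 1):
    r = np.corrcoef(gebv[:, t], truth.true_breeding_values[:, t])[0, 1]
    print(f"trait {t + 1}: corr(GEBV, true BV) = {r:.3f}")
# Estimates carry sampling noise of a single modest dataset; the standard
# errors from the inverse AI matrix quantify exactly that.
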