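# Methods

This note documents the statistical model, the algorithms and the numerical
choices behind `ssgblup`, and what the synthetic-data generator does and
does not emulate.

## Model

Two traits are analysed jointly with the linear animal model

    y = Xβ + Zα + e

per trait, stacked trait-major. Fixed effects per trait are a categorical
contemporary group (one dummy per level with records; no explicit
intercept) and a linear age covariate, centred within trait so it is
orthogonal to the group means. The additive genetic effects over the full
pedigree follow α ~ N(0, G0 ⊗ H) with G0 the 2×2 genetic covariance
matrix. Residuals are independent across animals with per-animal covariance
R0 restricted to the traits that animal actually has records for; this
handles the nested record structure (trait 1 measured on a subset of the
trait-2 animals) exactly, with no data augmentation.

### The single-step relationship matrix

H is never formed; its inverse is assembled directly:

    H⁻¹ = A⁻¹ + [0 0; 0 τG*⁻¹ − ωA22⁻¹]

* **A⁻¹** by Henderson's rules with inbreeding: each animal contributes
  1/d_i to its own diagonal, −0.5/d_i to animal–parent pairs and 0.25/d_i
  to parent–parent pairs, with Mendelian-sampling coefficient
  d_i = 0.5 − 0.25(F_s + F_d) (both parents known),
  0.75 − 0.25F_p (one parent), 1 (founder).
* **F** by the Meuwissen–Luo ancestor-tracing algorithm
  (a_ii = Σ_j T_ij²·d_j), which never forms A and scales to very large
  pedigrees.
* **A22** (genotyped block) by slicing the tabular A for ordinary problem
  sizes; above a size threshold by the Schur complement of the sparse A⁻¹,
  A22⁻¹ = Ainv22 − Ainv21·Ainv11⁻¹·Ainv12, so the full A is never
  materialised.
* **G** = Z·D·Z′/k with Z the dosage matrix centred by twice the observed
  allele frequency, D a diagonal SNP-weight matrix (identity unless the
  GWAS re-weighting supplies one) and k = 2Σp(1−p). Missing dosages are
  imputed to the column mean 2p before centring. Because centring with
  observed frequencies makes G·1 = 0 (exactly singular), the working
  matrix is the blend G* = 0.95·G + 0.05·A22, whose Cholesky is checked at
  construction. τ = 1.0 and ω = 0.7 are defaults, both overridable; they
  rescale the genomic and pedigree information in the genotyped block and
  are treated as user inputs, not re-derived.

k is held at its unweighted value across GWAS re-weighting iterations so
the scale of G — and hence of the estimated genetic variance — stays
comparable between iterations.

## AI-REML

The six free parameters are the elements of G0 and R0. The update is a
Newton step whose curvature matrix is the average information

    AI_ij = ½·y′P(∂V/∂θ_i)P(∂V/∂θ_j)Py

and whose gradient is exact:

    ∂(−2logL)/∂G0_kl = n·tr(G0⁻¹E_kl) − tr((G0⁻¹E_klG0⁻¹ ⊗ H⁻¹)·C^{αα})
                        − â′(G0⁻¹E_klG0⁻¹ ⊗ H⁻¹)â
    ∂(−2logL)/∂R0_kl = Σ_i tr(R0_i⁻¹E_kl,i) − tr(S·∂R/∂θ) − ê′R⁻¹E_klR⁻¹ê

with C^{αα} the random-effect block of the inverse MME coefficient matrix
and S = R⁻¹T·C⁻¹·T′R⁻¹ evaluated per animal. (Both formulas were verified
against central finite differences of the likelihood during development.)
The working vectors for the AI matrix use the identity
(E_kl ⊗ H)(G0⁻¹ ⊗ H⁻¹)â = (E_klG0⁻¹ ⊗ I)â, so H itself is never needed.
−2logL = log|R| + n·log|G0| + 2log|H| + log|C| + y′Py up to a constant;
log|H| is computed once per fit from a sparse LU of H⁻¹.

Numerical choices, in the order they matter in practice:

* **Parameterisation.** Steps are taken on the Cholesky factors of G0 and
  R0 (gradient and AI mapped through the analytic Jacobian), so both
  matrices stay positive semi-definite by construction and no step can
  leave the parameter space.
* **Line search.** A step is accepted only if −2logL does not increase;
  otherwise it is halved (up to 10 times). The accepted-trajectory
  likelihood is therefore monotone, which the test suite asserts.
* **Boundaries.** Cholesky diagonals are floored at 1e-6·√scale. A
  diagonal heading below its floor is pinned and removed from the Newton
  system (active set) — otherwise its vanishing Jacobian column makes the
  damped step explode. Each coordinate's step is additionally capped at
  twice its own scale. Estimates at the floor are flagged `boundary`, not
  treated as errors.
* **Boundary restart.** A fit that converges with |r| ≥ 0.995 for either
  covariance matrix is refit once from the converged point with the
  covariance pulled to 0.85 of its value, keeping whichever solution has
  the better likelihood. On the |r_G| = 1 ridge the first-order
  Cholesky-scale curvature is blind (the off-diagonal factor enters the
  natural parameters quadratically), and this restart reliably escapes the
  resulting stalls at the cost of one extra pass.
* **Convergence.** Maximum relative parameter change below `tol` (default
  1e-8) on a full-length, uncapped step; or likelihood flat to ~1e-6
  relative over three accepted steps (boundary creep); or no improving
  step at line-search precision.
* **Starting values.** Half the raw phenotypic (co)variance to each of G0
  and R0, the phenotypic covariance clipped to 0.9 of its bound.
* **Standard errors.** Inverse of the natural-scale AI matrix at the
  optimum; h² and r_G SEs by the first-order delta method. At a boundary
  these are approximations of convenience, as in standard REML software.

The MME are solved by dense Cholesky up to ~12k unknowns and by
Jacobi-preconditioned conjugate gradients (relative residual < 1e-10)
above that.

## Weighted-ssGBLUP GWAS

For each trait separately: solve the bivariate evaluation, back-solve the
genotyped animals' GEBVs into SNP effects û = k⁻¹·D·Z′·G*⁻¹·â, convert to
weights d_i = û_i²·2p_i(1−p_i) normalised to mean 1, rebuild G with the new
D, and repeat — three iterations by default, variance components held fixed
at their REML estimates. With the unblended G the reconstruction Z·û = â is
an algebraic identity (asserted in the tests); with the blended G* used in
production it holds approximately.

Window signal: for every run of 10 adjacent SNPs within a chromosome
(stride 1), the variance over genotyped animals of Z_w·û_w, expressed as a
percentage of Var(Z·û) — the total genomic variance — so a single window
covering every SNP gives exactly 100%. Trailing windows shorter than 10
SNPs at chromosome ends are dropped rather than padded, avoiding deflated
spans. Windows above 1% are reported, sorted within trait. The denominator
choice (genomic variance rather than the REML σ²a) keeps the decomposition
self-consistent; with dense panels the two differ by the part of pedigree
variance not captured by markers.

## Annotation

Genes are read from GFF3 (`gene` rows only, 1-based inclusive coordinates
preserved); QTL intervals from BED (0-based half-open, converted on
input). A gene is a candidate for a window when its body intersects the
window span extended by ±100 kb, strand ignored. The interval engine is a
per-chromosome sorted array with binary search; at typical window counts
(tens) and gene counts (tens of thousands) nothing faster is needed. An
optional hypergeometric over-representation test for user-supplied gene
sets is included as a labelled extra; it is not a pathway-database
analysis.

## Synthetic-data generator

The generator emulates the structure of the motivating data, not any real
genome:

* **Pedigree:** founders plus discrete generations of random sire×dam
  matings (one mating per dam per generation), sexes alternating. Defaults
  produce ≈4130 animals from 1030 founders over five generations.
* **Genotypes:** gene dropping. Founder alleles are Bernoulli(p) with p
  uniform on the configured range; each meiosis recombines with
  per-interval probabilities from Haldane's map at 1 cM/Mb (Poisson model,
  no interference, implemented as one cumulative-XOR pass per gamete with
  switch probability ½ at chromosome starts).
* **Breeding values:** infinitesimal mode draws exactly from N(0, G0 ⊗ A)
  via the pedigree recursion a_i = ½(a_s+a_d) + m_i with
  m_i ~ N(0, d_i·G0); QTL mode sums effects at sampled marker loci,
  rescaled so realised per-trait variances match G0 exactly (the realised
  correlation then matches the target only in expectation), optionally
  concentrating a set fraction of variance on one major locus.
* **Phenotypes:** trait mean + i.i.d. normal contemporary-group effect +
  age slope × centred uniform age + breeding value + bivariate normal
  residual. Trait-2 records are sampled from females; trait-1 records are
  a nested subsample, mirroring an assay run only on part of the scanned
  animals. Genotyped animals are chosen phenotyped-females-first.
* **Determinism:** every stage derives its stream from the single config
  seed via `SeedSequence([seed, stage])`; identical configs give
  bit-identical outputs.

What it does **not** emulate: selection or assortative mating, genotyping
error, linkage-disequilibrium structure beyond what random mating over a
handful of generations creates, minor-allele-frequency spectra of real
chips, X-chromosome inheritance, or heterogeneous contemporary-group
sizes. Passing recovery tests on these data therefore demonstrates
estimator correctness under the assumed model, not robustness to the ways
real data violate it.

## Validation studies and problem sizes

The reference studies in `ssgblup.study` use designs scaled so a full
validation run completes comfortably on one core: recovery replicates use
1500 pedigree animals (250 founders, five generations), 2000 SNPs on 10
chromosomes, ~375 trait-1 and ~1050 trait-2 records and ~600 genotyped
animals — preserving the motivating study's record-to-pedigree ratios —
and are repeated ten times; the GWAS power study uses 1000 animals and
1000 SNPs with a planted 30%-of-variance QTL. REML recovery replicates use
`tol = 1e-6`; at that tolerance the estimates are stable to well past the
precision at which they are compared.

## Known limitations

* Exactly two traits; maternal and permanent-environment effects, genetic
  groups and metafounders are out of scope.
* AI-REML standard errors at parameter boundaries are approximate.
* The weighted GWAS reports window variance shares, not calibrated
  p-values; the 1% threshold is a reporting convention, not a significance
  test.
* The PLINK codec handles the common SNP-major BED layout only.
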