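"""Genotype QC and the VanRaden genomic relationship matrix.

Dosages code the count of the A1 allele per SNP (0/1/2, NaN = missing).
The genomic relationship matrix is G = Z·D·Z′/k with Z the column-centred
dosages (2p subtracted, observed frequencies), D an optional diagonal SNP
weight matrix (identity when unweighted), and k = 2·Σ p(1−p).  To keep the
mixed-model system invertible G is blended with the pedigree block A22
(default 0.95·G + 0.05·A22).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix


class GenomicsError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals × SNPs dosage matrix with a marker map.

    ``dosages`` is float with values {0, 1, 2, NaN}.  ``marker_map`` has
    columns snp_id, chrom, bp with bp strictly increasing within chromosome
    (chromosome codes above ``n_autosomes`` or non-numeric are treated as
    sex/mitochondrial and removed by QC).
    """

    dosages: np.ndarray
    marker_map: pd.DataFrame
    animal_ids: list
    n_autosomes: int = 29

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animal_ids), len(self.marker_map)):
            raise GenomicsError("dosage shape does not match animal/marker counts")
        mm = self.marker_map.reset_index(drop=True)
        for chrom, grp in mm.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise GenomicsError(f"bp not strictly increasing on chromosome {chrom}")
        self.marker_map = mm

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(a, s)],
            marker_map=self.marker_map.iloc[s].reset_index(drop=True),
            animal_ids=[self.animal_ids[i] for i in a],
            n_autosomes=self.n_autosomes,
        )

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.animal_ids,
                          columns=self.marker_map["snp_id"])
        df.index.name = "animal"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path, marker_map: pd.DataFrame, n_autosomes: int = 29):
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(dosages=df.to_numpy(dtype=float), marker_map=marker_map,
                   animal_ids=df.index.tolist(), n_autosomes=n_autosomes)


@dataclass
class QcReport:
    """Per-criterion removal counts; precedence order is the field order."""

    n_snps_in: int
    n_animals_in: int
    removed_non_autosomal: int = 0
    removed_animal_call_rate: int = 0  # animals
    removed_snp_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_snps_out: int = 0
    n_animals_out: int = 0
    removed_snp_ids: dict = field(default_factory=dict)
    removed_animal_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("non_autosomal", "snp", self.removed_non_autosomal),
            ("animal_call_rate", "animal", self.removed_animal_call_rate),
            ("snp_call_rate", "snp", self.removed_snp_call_rate),
            ("maf", "snp", self.removed_maf),
            ("hwe_deviation", "snp", self.removed_hwe),
            ("surviving", "snp", self.n_snps_out),
            ("surviving", "animal", self.n_animals_out),
        ]
        return pd.DataFrame(rows, columns=["criterion", "dimension", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _is_autosomal(chrom, n_autosomes: int) -> bool:
    try:
        c = int(chrom)
    except (TypeError, ValueError):
        return False
    return 1 <= c <= n_autosomes


def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.05,
              snp_call_min: float = 0.90, animal_call_min: float = 0.90,
              hwe_dev_max: float = 0.15, autosomes_only: bool = True,
              ) -> tuple[GenotypeMatrix, QcReport]:
    """Marker/sample quality control.

    Removal precedence: non-autosomal SNPs → animals by call rate → SNPs by
    call rate → MAF → Hardy–Weinberg deviation, where the HWE statistic is
    |observed heterozygote frequency − 2p(1−p)| on non-missing calls.  Each
    later criterion is evaluated on the matrix surviving the earlier ones.
    """
    rep = QcReport(n_snps_in=geno.n_snps, n_animals_in=geno.n_animals)
    cur = geno

    if autosomes_only:
        keep = np.array([_is_autosomal(c, geno.n_autosomes)
                         for c in cur.marker_map["chrom"]])
        rep.removed_non_autosomal = int((~keep).sum())
        rep.removed_snp_ids["non_autosomal"] = cur.marker_map.loc[~keep, "snp_id"].tolist()
        cur = cur.subset(snp_idx=np.where(keep)[0])

    called = ~np.isnan(cur.dosages)
    a_rate = called.mean(axis=1) if cur.n_snps else np.ones(cur.n_animals)
    keep_a = a_rate >= animal_call_min
    rep.removed_animal_call_rate = int((~keep_a).sum())
    rep.removed_animal_ids = [cur.animal_ids[i] for i in np.where(~keep_a)[0]]
    cur = cur.subset(animal_idx=np.where(keep_a)[0])

    called = ~np.isnan(cur.dosages)
    s_rate = called.mean(axis=0) if cur.n_animals else np.ones(cur.n_snps)
    keep_s = s_rate >= snp_call_min
    rep.removed_snp_call_rate = int((~keep_s).sum())
    rep.removed_snp_ids["snp_call_rate"] = cur.marker_map.loc[~keep_s, "snp_id"].tolist()
    cur = cur.subset(snp_idx=np.where(keep_s)[0])

    p = allele_frequencies(cur)
    maf = np.minimum(p, 1 - p)
    keep_s = maf >= maf_min
    rep.removed_maf = int((~keep_s).sum())
    rep.removed_snp_ids["maf"] = cur.marker_map.loc[~keep_s, "snp_id"].tolist()
    cur = cur.subset(snp_idx=np.where(keep_s)[0])
    p = p[keep_s]

    # heterozygote frequency among non-missing calls
    called = ~np.isnan(cur.dosages)
    het = np.where(called.sum(axis=0) > 0,
                   (cur.dosages == 1).sum(axis=0) / np.maximum(called.sum(axis=0), 1), 0.0)
    dev = np.abs(het - 2 * p * (1 - p))
    keep_s = dev <= hwe_dev_max
    rep.removed_hwe = int((~keep_s).sum())
    rep.removed_snp_ids["hwe"] = cur.marker_map.loc[~keep_s, "snp_id"].tolist()
    cur = cur.subset(snp_idx=np.where(keep_s)[0])

    rep.n_snps_out = cur.n_snps
    rep.n_animals_out = cur.n_animals
    if cur.n_snps == 0:
        raise GenomicsError(f"all SNPs removed by QC; report: {rep.to_frame().to_dict('records')}")
    return cur, rep


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Observed A1 frequency per SNP: mean dosage over non-missing calls / 2."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(geno.dosages, axis=0) / 2.0
    return np.where(np.isnan(p), 0.0, p)


def center_genotypes(geno: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    """Z = dosage − 2p, missing dosages imputed to the column mean 2p."""
    M = geno.dosages.copy()
    miss = np.isnan(M)
    if miss.any():
        M[miss] = np.broadcast_to(2 * p, M.shape)[miss]
    return M - 2 * p


def vanraden_k(p: np.ndarray) -> float:
    return float(2.0 * np.sum(p * (1 - p)))


def build_G(geno: GenotypeMatrix, p: np.ndarray | None = None,
            weights: np.ndarray | None = None) -> RelationshipMatrix:
    """G = Z·D·Z′/k.  ``weights`` is the diagonal of D (identity if None).

    k = 2Σp(1−p) is deliberately independent of the weights so G keeps a
    comparable scale across GWAS re-weighting iterations.
    """
    if p is None:
        p = allele_frequencies(geno)
    k = vanraden_k(p)
    if k <= 0:
        raise GenomicsError("k = 2*sum(p(1-p)) is zero: no polymorphic SNPs")
    Z = center_genotypes(geno, p)
    if weights is None:
        G = Z @ Z.T / k
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (geno.n_snps,):
            raise GenomicsError("weight vector length != SNP count")
        if np.any(w < 0):
            raise GenomicsError("SNP weights must be non-negative")
        G = (Z * w) @ Z.T / k
    return RelationshipMatrix(values=(G + G.T) / 2, ids=list(geno.animal_ids), kind="G_raw")


def blend_G(G_raw: RelationshipMatrix, A22: RelationshipMatrix,
            g_weight: float = 0.95, a_weight: float = 0.05) -> RelationshipMatrix:
    """Convex blend G* = g_weight·G + a_weight·A22, checked invertible."""
    if list(G_raw.ids) != list(A22.ids):
        raise GenomicsError("G and A22 id order mismatch")
    Gb = g_weight * G_raw.values + a_weight * A22.values
    try:
        np.linalg.cholesky(Gb)
    except np.linalg.LinAlgError as e:
        raise GenomicsError("blended G is not positive definite") from e
    return RelationshipMatrix(values=Gb, ids=list(G_raw.ids), kind="G_blended")


def genomic_inbreeding(G_raw: RelationshipMatrix) -> float:
    """Mean of diag(G) − 1, the genomic analogue of mean pedigree F."""
    return float(np.mean(np.diag(G_raw.values)) - 1.0)
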