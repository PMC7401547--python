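"""Minimal PLINK 1 binary (BED/BIM/FAM) reader and writer.

Implements the SNP-major 2-bit layout directly with numpy bit operations.
Dosage convention: the stored two-bit code is mapped to the count of the A1
allele — 0b00 → 2, 0b10 → 1, 0b11 → 0, 0b01 → missing (NaN) — matching how
PLINK itself counts A1 in --recode A output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode

# two-bit code -> A1 dosage
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write prefix.bed/.bim/.fam for an animals × SNPs dosage matrix."""
    prefix = Path(prefix)
    n = geno.n_animals
    codes = np.full(geno.dosages.shape, 0b01, dtype=np.uint8)  # missing
    for dose, code in _DOSE_TO_CODE.items():
        codes[geno.dosages == dose] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((geno.n_snps, n_bytes), dtype=np.uint8)
    for shift in range(4):
        chunk = codes[shift::4, :].T  # snp-major
        packed[:, : chunk.shape[1]] |= chunk.astype(np.uint8) << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    mm = geno.marker_map
    bim = pd.DataFrame({
        "chrom": mm["chrom"], "snp_id": mm["snp_id"], "cm": 0.0,
        "bp": mm["bp"], "a1": "A", "a2": "B",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": geno.animal_ids, "iid": geno.animal_ids,
        "father": 0, "mother": 0, "sex": 0, "phen": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)


def read_plink(prefix, n_autosomes: int = 29) -> GenotypeMatrix:
    """Read prefix.bed/.bim/.fam back into a GenotypeMatrix."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "phen"])
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "bp", "a1", "a2"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1 BED file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dos = _CODE_TO_DOSE[codes[:, :n]].T  # animals x snps
    mm = pd.DataFrame({"snp_id": bim["snp_id"], "chrom": bim["chrom"], "bp": bim["bp"]})
    return GenotypeMatrix(dosages=dos, marker_map=mm,
                          animal_ids=fam["iid"].tolist(), n_autosomes=n_autosomes)
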