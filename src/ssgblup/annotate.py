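"""Candidate-gene and QTL-interval annotation of GWAS windows.

Genes come from a GFF3 file (rows of type ``gene``; 1-based inclusive
coordinates preserved) and are assigned to a window when the gene body
intersects the window span extended by a flanking distance on both sides
(default ±100 kb, a linkage-disequilibrium-scale neighbourhood).  QTL
intervals are read from BED (0-based half-open, converted to 1-based
inclusive internally).  Strand is ignored for distance.  The interval
engine is a per-chromosome sorted array with binary search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class AnnotationError(ValueError):
    pass


@dataclass
class GeneRecord:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self):
        if self.end < self.start:
            raise AnnotationError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})")


def load_genes(gff3_path) -> list[GeneRecord]:
    """Parse ``gene``-type rows of a GFF3 file via gffutils (in-memory db).

    Coordinates stay 1-based inclusive (the GFF3 convention).  Duplicate
    gene ids and end < start are rejected; a malformed attribute column is
    reported with its line number.
    """
    import gffutils

    # pre-scan for malformed attribute columns so the error carries a line number
    with open(gff3_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise AnnotationError(
                    f"{gff3_path}: line {ln}: expected 9 tab-separated columns, "
                    f"got {len(parts)}")
            if parts[2] == "gene" and "=" not in parts[8]:
                raise AnnotationError(
                    f"{gff3_path}: line {ln}: malformed attribute column "
                    f"{parts[8]!r}")
    try:
        db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                                merge_strategy="error", keep_order=True)
    except gffutils.exceptions.EmptyInputError:
        return []
    except Exception as e:  # includes sqlite duplicate-id errors
        raise AnnotationError(f"{gff3_path}: {e}") from e
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for g in db.features_of_type("gene"):
        if g.id in seen:
            raise AnnotationError(f"duplicate gene id {g.id!r}")
        seen.add(g.id)
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(GeneRecord(gene_id=g.id, gene_name=name, chrom=str(g.seqid),
                                start=int(g.start), end=int(g.end),
                                strand=g.strand or "."))
    return genes


def _by_chrom(genes: list[GeneRecord]) -> dict:
    out: dict[str, tuple] = {}
    for chrom in {g.chrom for g in genes}:
        sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
        out[chrom] = (np.array([g.start for g in sub]),
                      np.array([g.end for g in sub]), sub)
    return out


def annotate_windows(windows: pd.DataFrame, genes: list[GeneRecord],
                     flank_bp: int = 100_000) -> pd.DataFrame:
    """Assign genes to windows: gene [start, end] intersects
    [window.start − flank, window.end + flank] on the same chromosome.

    ``windows`` needs columns chrom, start_bp, end_bp (as produced by
    ``gwas.report_windows``); returns a copy with a ``genes`` column holding
    comma-joined gene names ('-' when none).
    """
    index = _by_chrom(genes)
    gene_chroms = set(index)
    win_chroms = {str(c) for c in windows["chrom"].unique()}
    unmatched = win_chroms - {str(c) for c in gene_chroms}
    if unmatched and len(gene_chroms):
        warnings.warn(f"window chromosomes with no genes in the annotation: "
                      f"{sorted(unmatched)}")
    hits_col = []
    names_col = []
    for _, w in windows.iterrows():
        chrom = next((c for c in gene_chroms if str(c) == str(w["chrom"])), None)
        hits: list[GeneRecord] = []
        if chrom is not None:
            starts, ends, sub = index[chrom]
            lo = int(w["start_bp"]) - flank_bp
            hi = int(w["end_bp"]) + flank_bp
            # overlap iff gene.start <= hi and gene.end >= lo; genes sorted by
            # start, so cut the tail with searchsorted and scan the head
            cut = np.searchsorted(starts, hi, side="right")
            hits = [sub[i] for i in range(cut) if ends[i] >= lo]
        hits_col.append([g.gene_id for g in hits])
        names_col.append(", ".join(g.gene_name for g in hits) if hits else "-")
    out = windows.copy()
    out["gene_ids"] = hits_col
    out["genes"] = names_col
    return out


def read_qtl_bed(bed_path) -> pd.DataFrame:
    """BED intervals → 1-based inclusive frame (chrom, start, end, name)."""
    rows = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise AnnotationError(
                    f"{bed_path}: line {ln}: BED needs >= 3 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise AnnotationError(
                    f"{bed_path}: line {ln}: non-integer coordinates")
            if end0 <= start0:
                raise AnnotationError(
                    f"{bed_path}: line {ln}: empty or inverted interval")
            name = parts[3] if len(parts) > 3 else f"qtl_{ln}"
            rows.append((parts[0], start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_qtl_bed(df: pd.DataFrame, path) -> None:
    """Inverse of ``read_qtl_bed`` (1-based inclusive → 0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{r['name']}\n")


def overlap_qtl(windows: pd.DataFrame, qtl: pd.DataFrame) -> pd.DataFrame:
    """Window × QTL intersection report with overlap length in bp.

    Touching-but-not-overlapping intervals (zero shared bases on the 1-based
    inclusive scale) are not hits.
    """
    rows = []
    for wi, w in windows.iterrows():
        for _, q in qtl.iterrows():
            if str(w["chrom"]) != str(q["chrom"]):
                continue
            lo = max(int(w["start_bp"]), int(q["start"]))
            hi = min(int(w["end_bp"]), int(q["end"]))
            if hi >= lo:
                rows.append((wi, w["chrom"], int(w["start_bp"]), int(w["end_bp"]),
                             q["name"], int(q["start"]), int(q["end"]), hi - lo + 1))
    return pd.DataFrame(rows, columns=["window_index", "chrom", "start_bp",
                                       "end_bp", "qtl", "qtl_start", "qtl_end",
                                       "overlap_bp"])


def hypergeom_enrichment(candidate_genes: set, gene_set: set,
                         universe: set) -> dict:
    """Optional over-representation test of a user-supplied gene set among
    the candidate genes (hypergeometric upper tail).  A generic extra, not a
    pathway-database analysis."""
    from scipy.stats import hypergeom

    cand = candidate_genes & universe
    hits = cand & gene_set
    M, n, N = len(universe), len(gene_set & universe), len(cand)
    p = float(hypergeom.sf(len(hits) - 1, M, n, N)) if N else 1.0
    return {"n_universe": M, "n_set": n, "n_candidates": N,
            "n_hits": len(hits), "p_value": p}
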