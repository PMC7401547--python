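"""Annotate GWAS windows with candidate genes and QTL intervals.

Uses a toy GFF3 annotation and a toy QTL BED file to show the ±100 kb
flanking rule (genes whose body intersects the window extended by 100 kb on
each side are candidates) and the interval-overlap report.
"""

import pandas as pd

from ssgblup import annotate_windows, load_genes, overlap_qtl, read_qtl_bed

GFF = """##gff-version 3
1\ttoy\tgene\t950000\t960000\t.\t+\t.\tID=gene:G1;Name=FERT1
1\ttoy\tgene\t1450000\t1500000\t.\t-\t.\tID=gene:G2;Name=FERT2
2\ttoy\tgene\t100000\t120000\t.\t+\t.\tID=gene:G3;Name=OTHER
"""
BED = "1\t1040000\t1070000\tknown_fertility_qtl\n"

with open("/tmp/toy_genes.gff3", "w") as fh:
    fh.write(GFF)
with open("/tmp/toy_qtl.bed", "w") as fh:
    fh.write(BED)

windows = pd.DataFrame({
    "trait": ["trait2", "trait2"],
    "chrom": ["1", "1"],
    "start_bp": [1_050_000, 2_000_000],
    "end_bp": [1_060_000, 2_010_000],
    "pct_variance": [4.2, 1.3],
})

genes = load_genes("/tmp/toy_genes.gff3")
print(f"loaded {len(genes)} genes")
annotated = annotate_windows(windows, genes, flank_bp=100_000)
print(annotated[["chrom", "start_bp", "end_bp", "pct_variance", "genes"]]
      .to_string(index=False))
# FERT1 ends 90 kb before the first window, so it is a candidate at the
# 100 kb flank; FERT2 starts 390 kb after it and is not.

qtl = read_qtl_bed("/tmp/toy_qtl.bed")
print("\nQTL overlap (BED half-open coordinates converted to 1-based):")
print(overlap_qtl(windows, qtl).to_string(index=False))
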