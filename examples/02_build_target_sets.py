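"""Build TF target gene sets from an annotation and TFBS intervals.

A gene is a potential target of a TF when one of the TF's binding sites
falls in the gene's promoter window: 5000 bp upstream of the outermost
transcription start site through the end of the first exon.
"""

import tempfile
from pathlib import Path

from tftea.gene_sets import (map_tfbs_to_targets, read_gene_models,
                             read_tfbs_bed, target_window)

GFF3 = """##gff-version 3
chr1\tdemo\tgene\t10001\t12000\t.\t+\t.\tID=geneA
chr1\tdemo\tmRNA\t10001\t12000\t.\t+\t.\tID=txA;Parent=geneA
chr1\tdemo\texon\t10001\t10200\t.\t+\t.\tID=exA1;Parent=txA
chr1\tdemo\tgene\t30001\t32000\t.\t-\t.\tID=geneB
chr1\tdemo\tmRNA\t30001\t32000\t.\t-\t.\tID=txB;Parent=geneB
chr1\tdemo\texon\t31801\t32000\t.\t-\t.\tID=exB1;Parent=txB
"""
# BED: chrom, start, end, TF name
BED = ("chr1\t6000\t6050\tMYC\t100\t.\n"       # in geneA's window
       "chr1\t33000\t33050\tMYC\t90\t.\n"      # in geneB's window (- strand)
       "chr1\t500\t600\tGATA1\t80\t.\n")       # outside every window

with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "genes.gff3"
    bed = Path(tmp) / "tfbs.bed"
    gff.write_text(GFF3)
    bed.write_text(BED)
    genes = read_gene_models(gff)
    tfbs = read_tfbs_bed(bed)

for g in genes:
    lo, hi = target_window(g, upstream=5000)
    print(f"{g.gene_id} ({g.strand} strand): TSS {g.tss}, "
          f"promoter window [{lo}, {hi})")

coll = map_tfbs_to_targets(genes, tfbs, upstream=5000)
for tf in coll:
    print(f"{tf} -> targets {sorted(coll[tf])}")
print("GATA1 is absent: its only site misses every promoter window,")
print("and TFs without targets are dropped from the collection.")
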