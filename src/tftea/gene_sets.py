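"""Build TF -> target gene sets from a gene annotation and TFBS intervals.

A gene is a potential target of a TF if one of the TF's binding sites
overlaps the gene's promoter window: from ``upstream`` bp (default 5000)
upstream of the outermost transcription start site through the 3' end of
the first exon, on the transcribed strand.  Coordinates are handled
internally as 0-based half-open; GFF3 (1-based closed) is converted on
read, BED is taken as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TFTargetCollection

__all__ = ["GeneModel", "TFBSRecord", "target_window", "map_tfbs_to_targets",
           "read_gene_models", "read_tfbs_bed"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: outermost TSS and the first exon of the
    transcript that carries it.  Intervals are 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    first_exon: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        s, e = self.first_exon
        if not s < e:
            raise ValueError(f"{self.gene_id}: empty first-exon interval [{s},{e})")
        # the TSS is the 5' edge of the first exon on the gene's strand
        expected = s if self.strand == "+" else e
        if self.tss != expected:
            raise ValueError(
                f"{self.gene_id}: TSS {self.tss} does not match the 5' edge "
                f"of the first exon {self.first_exon} on strand {self.strand}"
            )


@dataclass(frozen=True)
class TFBSRecord:
    """One mapped binding-site interval for a TF (0-based half-open)."""

    tf_name: str
    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.tf_name}: start {self.start} must be < end {self.end}")


def target_window(gene: GeneModel, upstream: int = 5000) -> tuple[int, int]:
    """Promoter window of a gene: ``upstream`` bp 5' of the outermost TSS
    through the 3' end of the first exon, clipped at position 0.

    On the + strand this is ``[tss - upstream, first_exon_end)``; on the
    - strand, ``[first_exon_start, tss + upstream)``.
    """
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    if gene.strand == "+":
        lo = max(0, gene.tss - upstream)
        hi = gene.first_exon[1]
    else:
        lo = gene.first_exon[0]
        hi = gene.tss + upstream
    return (lo, hi)


def map_tfbs_to_targets(genes: list[GeneModel], tfbs: list[TFBSRecord],
                        upstream: int = 5000,
                        provenance: str = "tfbs_window") -> TFTargetCollection:
    """Assign genes to TFs by >=1 bp overlap of a binding site with the
    gene's promoter window.  TFs that end up with no targets are
    omitted; TFBS on chromosomes absent from the annotation are skipped
    with a warning.  Output is independent of input record order.
    """
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        lo, hi = target_window(g, upstream)
        windows.setdefault(g.chrom, []).append((lo, hi, g.gene_id))

    win_arrays = {
        chrom: (np.array([w[0] for w in ws]), np.array([w[1] for w in ws]),
                np.array([w[2] for w in ws], dtype=object))
        for chrom, ws in windows.items()
    }
    sets: dict[str, set[str]] = {}
    missing_chroms: set[str] = set()
    for rec in tfbs:
        arrs = win_arrays.get(rec.chrom)
        if arrs is None:
            missing_chroms.add(rec.chrom)
            continue
        lo, hi, ids = arrs
        hit = (rec.start < hi) & (rec.end > lo)
        if hit.any():
            sets.setdefault(rec.tf_name, set()).update(ids[hit])
    if missing_chroms:
        warnings.warn(
            f"TFBS on chromosome(s) absent from the annotation skipped: "
            f"{sorted(missing_chroms)}", stacklevel=2)
    return TFTargetCollection(sets=sets, provenance=provenance)


# ---------------------------------------------------------------------------
# readers


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Extract one GeneModel per gene from a GFF3 annotation.

    For each gene the outermost TSS is the most 5' transcript start on
    the gene's strand, and the first exon is the 5'-most exon of that
    same transcript.  GFF3 1-based closed coordinates become 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        strand = gene.strand
        if strand not in ("+", "-"):
            log.warning("gene %s: unstranded, skipped", gene.id)
            continue
        best_tx = None
        best_tss = None
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            tss = tx.start - 1 if strand == "+" else tx.end
            if best_tss is None or (strand == "+" and tss < best_tss) \
                    or (strand == "-" and tss > best_tss):
                best_tss, best_tx = tss, tx
        if best_tx is None:
            continue
        exons = sorted(db.children(best_tx, featuretype="exon"),
                       key=lambda e: e.start)
        if not exons:
            continue
        first = exons[0] if strand == "+" else exons[-1]
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=strand,
            tss=best_tss, first_exon=(first.start - 1, first.end)))
    return models


def read_tfbs_bed(bed_path: str | Path) -> list[TFBSRecord]:
    """Read TFBS intervals from a BED file; column 4 is the TF name,
    column 5 (when present) the score."""
    df = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("TFBS BED needs >=4 columns (chrom, start, end, name)")
    records = []
    for row in df.itertuples(index=False):
        score = float(row[4]) if len(row) > 4 and pd.notna(row[4]) else None
        records.append(TFBSRecord(tf_name=str(row[3]), chrom=str(row[0]),
                                  start=int(row[1]), end=int(row[2]), score=score))
    return records
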