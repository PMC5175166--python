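"""Per-sample TF activity.

Each tumour sample's normalized expression is standardized against a
reference profile built from the normal samples: F_cg = (v_cg - m_g)/s_g,
where m_g and s_g are the per-gene mean and standard deviation over
normals.  Genes are then ranked by decreasing F_cg and the enrichment
test is applied per sample, giving a signed activity z-score
(sign(slope) * sqrt(Wald)) per TF per sample.  For paired designs the
fold change is the direct tumour-minus-normal difference on the
normalized log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import run_collection
from .io import TFTargetCollection
from .ranking import RankedList

__all__ = ["ReferenceProfile", "SampleActivityMatrix", "reference_profile",
           "sample_fold_changes", "paired_fold_changes", "personalized_activity"]


@dataclass
class ReferenceProfile:
    """Per-gene mean (m_g) and standard deviation (s_g) of normalized
    expression over the normal samples."""

    gene_ids: list[str]
    m: np.ndarray
    s: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if not (len(self.gene_ids) == self.m.size == self.s.size):
            raise ValueError("gene_ids, m and s must have equal length")
        if self.n_ref < 2:
            raise ValueError("reference profile needs >=2 normal samples")
        if np.any(self.s < 0):
            raise ValueError("negative standard deviation")


@dataclass
class SampleActivityMatrix:
    """TFs x samples activity (signed Wald z), with p and per-sample
    BH-adjusted p companions.  NaN marks untested entries."""

    activity: pd.DataFrame
    p: pd.DataFrame
    adj_p: pd.DataFrame
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def tf_names(self) -> list[str]:
        return self.activity.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.activity.columns.tolist()


def reference_profile(norm_normals: pd.DataFrame) -> ReferenceProfile:
    """Build the reference from normalized expression of >=2 normal
    samples (genes x samples); s_g uses the n-1 denominator."""
    if norm_normals.shape[1] < 2:
        raise ValueError("need >=2 normal samples for a reference profile")
    vals = norm_normals.to_numpy(dtype=float)
    return ReferenceProfile(
        gene_ids=[str(g) for g in norm_normals.index],
        m=vals.mean(axis=1),
        s=vals.std(axis=1, ddof=1),
        n_ref=norm_normals.shape[1])


def sample_fold_changes(v: pd.Series, ref: ReferenceProfile) -> tuple[pd.Series, list[str]]:
    """Standardized per-gene fold change of one tumour sample against
    the reference: F_cg = (v_cg - m_g)/s_g.

    Genes with s_g = 0 have no defined standardization and are dropped
    from the sample's universe; their ids come back as the drop log.
    """
    genes = set(v.index)
    ref_genes = set(ref.gene_ids)
    if genes != ref_genes:
        raise ValueError(
            f"gene universes differ: {len(genes - ref_genes)} only in sample, "
            f"{len(ref_genes - genes)} only in reference")
    v_arr = v.loc[ref.gene_ids].to_numpy(dtype=float)
    ok = ref.s > 0
    dropped = [g for g, keep in zip(ref.gene_ids, ok) if not keep]
    f = (v_arr[ok] - ref.m[ok]) / ref.s[ok]
    return pd.Series(f, index=np.asarray(ref.gene_ids, dtype=object)[ok]), dropped


def paired_fold_changes(v_tumour: pd.Series, v_normal: pd.Series) -> pd.Series:
    """Per-gene fold change for a matched tumour/normal pair: the
    difference on the normalized log scale."""
    if set(v_tumour.index) != set(v_normal.index):
        raise ValueError("paired samples must share the gene universe")
    return v_tumour - v_normal.loc[v_tumour.index]


def personalized_activity(norm_tumours: pd.DataFrame, ref: ReferenceProfile,
                          coll: TFTargetCollection, min_targets: int = 10,
                          predictor: str = "rank") -> SampleActivityMatrix:
    """Per-sample enrichment over a tumour cohort.

    For each tumour sample, genes are ranked by decreasing F_cg and the
    collection is tested; BH adjustment is per sample across its TFs.
    A sample whose fold changes cannot be computed is recorded as NaN
    columns rather than aborting the batch.
    """
    tf_names = sorted(coll.sets)
    samples = [str(s) for s in norm_tumours.columns]
    act = pd.DataFrame(math.nan, index=tf_names, columns=samples)
    pmat = pd.DataFrame(math.nan, index=tf_names, columns=samples)
    amat = pd.DataFrame(math.nan, index=tf_names, columns=samples)
    drop_log: dict[str, list[str]] = {}
    for s in samples:
        try:
            f, dropped = sample_fold_changes(norm_tumours[s], ref)
            drop_log[s] = dropped
            ranked = RankedList.from_statistics(f)
            results = run_collection(ranked, coll, min_targets=min_targets,
                                     predictor=predictor)
        except ValueError:
            drop_log[s] = []
            continue
        for r in results:
            if r.tested:
                act.loc[r.tf_name, s] = r.direction * math.sqrt(r.wald)
                pmat.loc[r.tf_name, s] = r.p
                amat.loc[r.tf_name, s] = r.adj_p
    return SampleActivityMatrix(activity=act, p=pmat, adj_p=amat,
                                dropped_genes=drop_log)
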