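"""Count normalization and the ranked differential-expression list.

Between-sample normalization uses the trimmed mean of M-values (TMM):
for each sample, log2 expression ratios (M-values) against a reference
sample are trimmed (30% on M, 5% on A) and averaged with inverse
asymptotic-variance weights; the exponentiated mean is the sample's
scaling factor.  Effective library sizes (library size x factor) then
feed a log2-CPM transform, and a per-gene two-group statistic (default
Welch t) produces the ranked gene list the enrichment test consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["RankedList", "tmm_factors", "normalize", "differential_rank",
           "welch_t", "read_rank", "write_rank"]


@dataclass
class RankedList:
    """Genes ordered by a per-gene differential statistic, descending.

    Larger statistic = more up in condition A versus B.  Rank 1 is the
    top of the list; ties in the statistic are broken by lexicographic
    gene id so the ordering is deterministic.
    """

    gene_ids: list[str]
    statistic: np.ndarray

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(self.gene_ids) != len(self.statistic):
            raise ValueError("gene_ids and statistic lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.statistic) > 0):
            raise ValueError("statistic must be non-increasing with rank")

    @classmethod
    def from_statistics(cls, stats: dict[str, float] | pd.Series) -> "RankedList":
        """Build a ranked list from an unordered gene -> statistic map."""
        items = sorted(stats.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(gene_ids=[g for g, _ in items],
                   statistic=np.array([v for _, v in items]))

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def ranks(self) -> dict[str, int]:
        """1-based rank per gene."""
        return {g: i + 1 for i, g in enumerate(self.gene_ids)}

    def reversed(self) -> "RankedList":
        return RankedList(list(reversed(self.gene_ids)), -self.statistic[::-1])


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              log_ratio_trim: float = 0.30, sum_trim: float = 0.05) -> float:
    """TMM log2 factor of one observation library against the reference."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        return 0.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method asymptotic variance of M
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.allclose(m, 0.0, atol=1e-10):
        return 0.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    w = 1.0 / v[keep2]
    return float(np.sum(w * m[keep2]) / np.sum(w))


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """Per-sample TMM scaling factors, geometric-mean centred to 1.

    When ``ref_sample`` is not given, the reference is the sample whose
    upper-quartile count fraction is closest to the mean upper quartile.
    Samples with a zero total count are rejected.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot == 0:
            raise ValueError(f"sample {cm.sample_ids[j]!r} has zero total count")
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                        for j in range(counts.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = cm.sample_ids.index(ref_sample)
    log_f = np.array([_tmm_pair(counts[:, j], counts[:, ref_idx])
                      for j in range(counts.shape[1])])
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def normalize(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2-CPM on effective library sizes (library size x TMM factor),
    with a prior count of 0.5: ``log2((c + 0.5)/(L_eff + 1) * 1e6)``."""
    if factors is None:
        factors = tmm_factors(cm)
    lib = cm.counts.sum(axis=0).astype(float)
    eff = lib * factors.loc[cm.sample_ids].to_numpy()
    logcpm = np.log2((cm.counts + 0.5) / (eff + 1.0) * 1e6)
    return pd.DataFrame(logcpm, index=cm.gene_ids, columns=cm.sample_ids)


# ---------------------------------------------------------------------------
# differential statistic and ranking


def welch_t(norm: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]) -> pd.Series:
    """Per-gene Welch t statistic, A minus B, on normalized values.

    A gene constant within both groups gets statistic 0 rather than 0/0.
    """
    a = norm[list(group_a)].to_numpy()
    b = norm[list(group_b)].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("Welch t needs >=2 samples per group")
    diff = a.mean(axis=1) - b.mean(axis=1)
    se2 = a.var(axis=1, ddof=1) / na + b.var(axis=1, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), 0.0)
    return pd.Series(t, index=norm.index, name="statistic")


def differential_rank(norm: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str],
                      stat: Callable[[pd.DataFrame, Sequence[str], Sequence[str]], pd.Series]
                      = welch_t) -> RankedList:
    """Rank genes by a per-gene two-group statistic (default Welch t),
    descending; larger = more up in A."""
    missing = (set(group_a) | set(group_b)) - set(norm.columns)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")
    s = stat(norm, group_a, group_b)
    return RankedList.from_statistics(s)


def read_rank(path) -> RankedList:
    """Read a two-column TSV (gene_id, statistic), e.g. an externally
    computed moderated-t, and rank it."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("rank file needs gene_id and statistic columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                  index=df.iloc[:, 0].astype(str))
    if s.index.duplicated().any():
        raise ValueError("duplicate gene ids in rank file")
    return RankedList.from_statistics(s)


def write_rank(ranked: RankedList, path) -> None:
    pd.DataFrame({"gene_id": ranked.gene_ids, "statistic": ranked.statistic}
                 ).to_csv(path, sep="\t", index=False)
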