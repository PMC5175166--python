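"""Readers and writers for the tabular formats the pipeline touches.

Counts are genes x samples TSV (first column gene ids, header row sample
ids), gene sets are GMT, clinical data is a TSV with at least
``sample_id``, ``time`` and ``event`` columns.  All readers enforce the
type invariants up front so downstream stages can assume clean data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TFTargetCollection",
    "ClinicalTable",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "tf_catalogue_names",
    "load_toy_catalogue",
]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts.
    group : dict, optional
        Per-sample label (e.g. ``"tumour"`` / ``"normal"``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        n_g, n_s = self.counts.shape
        if n_g != len(self.gene_ids) or n_s != len(self.sample_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids and {len(self.sample_ids)} sample ids"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} id(s): {', '.join(sorted(dupes))}")
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if self.group is not None:
            unknown = set(self.group) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def samples(self, label: str) -> list[str]:
        """Sample ids carrying the given group label."""
        if self.group is None:
            raise ValueError("no group labels attached")
        return [s for s in self.sample_ids if self.group.get(s) == label]


@dataclass
class TFTargetCollection:
    """Map from TF name to its set of target gene ids.

    Composite motifs (``MYC::MAX``, ``JUN::FOS`` ...) are single entries.
    """

    sets: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for tf, members in self.sets.items():
            if not members:
                raise ValueError(f"TF {tf!r} has an empty target set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, tf: str) -> set[str]:
        return self.sets[tf]

    def __eq__(self, other) -> bool:
        return isinstance(other, TFTargetCollection) and self.sets == other.sets


@dataclass
class ClinicalTable:
    """Per-sample survival time (days), event indicator and optional
    stage label and tumour purity fraction."""

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "time", "event")
    OPTIONAL = ("stage", "purity")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        dupes = _duplicates(df["sample_id"].tolist())
        if dupes:
            raise ValueError(f"duplicate sample id(s): {', '.join(sorted(dupes))}")
        if (df["time"] < 0).any():
            raise ValueError("negative survival time")
        bad = set(df["event"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"event values outside {{0,1}}: {sorted(bad)}")
        if "purity" in df.columns:
            p = df["purity"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise ValueError("purity outside [0,1]")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def has_purity(self) -> bool:
        return "purity" in self.data.columns and self.data["purity"].notna().any()

    def __len__(self) -> int:
        return len(self.data)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        (dup if i in seen else seen).add(i)
    return dup


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, group: dict[str, str] | None = None) -> CountMatrix:
    """Read a genes x samples TSV of integer counts.

    ``#`` comment lines are ignored; the first column holds gene ids and
    the header row holds sample ids.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    body = df.to_numpy()
    if body.size and not np.issubdtype(body.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy() & df.notna().to_numpy())
        if len(bad):
            g, s = bad[0]
            raise ValueError(
                f"non-numeric count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        df = coerced
    if (df.to_numpy() % 1 != 0).any():
        g, s = np.argwhere(df.to_numpy() % 1 != 0)[0]
        raise ValueError(
            f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy().astype(np.int64),
        group=group,
    )


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> TFTargetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Lines with no members are rejected (with their line number); the first
    description field encountered is kept as the collection's provenance.
    """
    sets: dict[str, set[str]] = {}
    provenance = ""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected at least name and description")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate TF name {name!r}")
            if not provenance:
                provenance = desc
            sets[name] = set(members)
    return TFTargetCollection(sets=sets, provenance=provenance)


def write_gmt(coll: TFTargetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(coll.sets):
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.provenance}\t{members}\n")


_CATALOGUE = "tf_catalogue.gmt"
_TOY_CATALOGUE = "tf_catalogue_toy.gmt"


def _data_path(name: str):
    return importlib.resources.files("tftea.data").joinpath(name)


def tf_catalogue_names() -> list[str]:
    """Names of the 52 Ensembl (GRCh38.p3) TFs bundled with the package.

    The bundled catalogue records names only (target membership depends on
    an annotation + TFBS build, see :mod:`tftea.gene_sets`), so it is read
    leniently here rather than through :func:`read_gmt`.
    """
    names: list[str] = []
    with _data_path(_CATALOGUE).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            names.append(line.split("\t")[0])
    return names


def load_toy_catalogue() -> TFTargetCollection:
    """The 52-TF catalogue with small synthetic target sets, for demos
    and tests that need a full-size collection without a TFBS build."""
    with importlib.resources.as_file(_data_path(_TOY_CATALOGUE)) as p:
        return read_gmt(p)


# ---------------------------------------------------------------------------
# clinical


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time, event and
    optionally stage and purity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    keep = [c for c in (*ClinicalTable.REQUIRED, *ClinicalTable.OPTIONAL) if c in df.columns]
    df = df[keep]
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False)
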