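"""Core data containers and file I/O.

The universal input is a :class:`CountTable`: a non-negative OTU × sample
matrix with unique row/column identifiers.  Orientation is fixed as
OTUs-in-rows, samples-in-columns everywhere in the package.  Raw tables
hold 64-bit integers; normalized or transformed tables hold floats and
carry ``is_raw=False`` so downstream methods can enforce raw-count
preconditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import skbio


class CountTableError(ValueError):
    """Raised for malformed count tables or count-table files."""


@dataclass
class CountTable:
    """OTU × sample count matrix.

    Parameters
    ----------
    otu_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray, shape (n_otus, n_samples)
        Non-negative counts; integer-valued when ``is_raw``.
    is_raw : bool
        True for raw integer counts, False after normalization or
        transformation.
    provenance : dict
        Free-form record of how the table was produced (seeds, configs).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    is_raw: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        dtype = np.int64 if self.is_raw else np.float64
        self.counts = np.asarray(self.counts)
        if self.is_raw:
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise CountTableError("raw count table contains non-integer values")
        self.counts = self.counts.astype(dtype)
        self._validate()

    def _validate(self):
        n_otu, n_samp = self.counts.shape
        if len(self.otu_ids) != n_otu or len(self.sample_ids) != n_samp:
            raise CountTableError("id lists do not match matrix shape")
        if n_otu < 1 or n_samp < 2:
            raise CountTableError("need at least 1 OTU and 2 samples")
        if len(set(self.otu_ids)) != n_otu:
            raise CountTableError("duplicate otu_ids")
        if len(set(self.sample_ids)) != n_samp:
            raise CountTableError("duplicate sample_ids")
        if not np.all(np.isfinite(self.counts)):
            raise CountTableError("non-finite counts")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise CountTableError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def copy(self, **overrides) -> "CountTable":
        kw = dict(
            otu_ids=list(self.otu_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts.copy(),
            is_raw=self.is_raw,
            provenance=dict(self.provenance),
        )
        kw.update(overrides)
        return CountTable(**kw)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass
class SampleMetadata:
    """Per-sample variables (design variable, strata, covariates)."""

    table: pd.DataFrame  # index = sample ids

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        self.table.index = self.table.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        col = self.table[name]
        if sample_ids is not None:
            col = col.loc[list(sample_ids)]
        if col.isna().any():
            raise ValueError(f"metadata column {name!r} has missing values")
        return col.to_numpy()

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


class PhyloTree:
    """Rooted phylogeny wrapping a scikit-bio ``TreeNode``.

    Branch lengths must be finite and >= 0 (zero-length branches occur
    in real inference output and are allowed); tip labels must be unique.
    """

    def __init__(self, tree: skbio.TreeNode):
        self.tree = tree
        tips = [t.name for t in tree.tips()]
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip labels in tree")
        for node in tree.traverse(include_self=False):
            bl = node.length
            if bl is None:
                node.length = 0.0
            elif not np.isfinite(bl) or bl < 0:
                raise ValueError(f"invalid branch length {bl!r} on node {node.name!r}")
        self.tip_names = tips

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))

    def require_tips(self, otu_ids: Iterable[str]):
        """Raise if any of *otu_ids* is not a tip of the tree."""
        missing = sorted(set(otu_ids) - set(self.tip_names))
        if missing:
            raise ValueError(f"OTUs absent from tree tips: {missing}")

    def tip_distances(self) -> skbio.DistanceMatrix:
        """Pairwise cophenetic (path-length) distances between tips."""
        return self.tree.tip_tip_distances()

    def write(self, path):
        self.tree.write(str(path))


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path, format: Literal["tsv", "biom-json"] = "tsv") -> CountTable:
    """Read a raw count table from TSV or dense BIOM-JSON.

    TSV dialect: first column OTU id, header row = sample ids, integer
    cells.  Negative or non-numeric cells raise an error naming the
    offending row and column.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> CountTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise CountTableError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise CountTableError(f"{path}: no data rows")
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    if len(set(otu_ids)) != len(otu_ids):
        raise CountTableError(f"{path}: duplicate OTU ids")
    if len(set(sample_ids)) != len(sample_ids):
        raise CountTableError(f"{path}: duplicate sample ids")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col].to_numpy()):
            try:
                x = float(val)
                if not x.is_integer():
                    raise ValueError
                counts[i, j] = int(x)
            except (TypeError, ValueError):
                raise CountTableError(
                    f"{path}: non-integer cell at row {otu_ids[i]!r}, column {sample_ids[j]!r}: {val!r}"
                ) from None
            if counts[i, j] < 0:
                raise CountTableError(
                    f"{path}: negative cell at row {otu_ids[i]!r}, column {sample_ids[j]!r}"
                )
    return CountTable(otu_ids, sample_ids, counts, is_raw=True,
                      provenance={"source": str(path), "format": "tsv"})


def _read_biom_json(path: Path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise CountTableError(f"{path}: only dense BIOM-JSON is supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.asarray(doc["data"])
    if np.any(counts < 0):
        raise CountTableError(f"{path}: negative cell in BIOM data")
    return CountTable(otu_ids, sample_ids, counts, is_raw=True,
                      provenance={"source": str(path), "format": "biom-json"})


def write_count_table(t: CountTable, path, format: Literal["tsv", "biom-json"] = "tsv"):
    """Write a count table; inverse of :func:`read_count_table`."""
    path = Path(path)
    if format == "tsv":
        df = t.to_dataframe()
        df.index.name = "#OTU_ID"
        df.to_csv(path, sep="\t")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [t.n_otus, t.n_samples],
            "rows": [{"id": o, "metadata": None} for o in t.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in t.sample_ids],
            "data": t.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    tree = skbio.TreeNode.read(str(path))
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Elementary statistics


def library_sizes(t: CountTable) -> np.ndarray:
    """Per-sample totals (sequencing depth): column sums of the matrix."""
    return t.counts.sum(axis=0)


def sparsity(t: CountTable, level: Literal["table", "per_otu"] = "table"):
    """Fraction of zero cells, table-wide or per OTU (share of samples at 0)."""
    zero = t.counts == 0
    if level == "table":
        return float(zero.mean())
    if level == "per_otu":
        return zero.mean(axis=1)
    raise ValueError(f"unknown level {level!r}")


def to_relative_abundance(t: CountTable) -> CountTable:
    """Total-sum scaling: divide each sample by its library size.

    Idempotent; every output column sums to 1.  A zero-total sample is
    an error (its composition is undefined).
    """
    totals = t.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        j = int(np.argmax(totals == 0))
        raise CountTableError(f"sample {t.sample_ids[j]!r} has zero total count")
    rel = t.counts / totals
    return CountTable(list(t.otu_ids), list(t.sample_ids), rel, is_raw=False,
                      provenance={**t.provenance, "normalization": "tss"})
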