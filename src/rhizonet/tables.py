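"""Data model and I/O for OTU tables, taxonomy, and sample metadata.

The central container is :class:`OtuTable`, an OTUs × samples matrix of
sequence counts (or relative abundances) with ordered, unique OTU and sample
identifiers. Tables circulate as tab-separated text (first column OTU id,
header row sample ids); a reader for the BIOM 1.0 JSON layout is provided
for convenience.

Marker-gene datasets rarefied to different depths (e.g. a 16S and an ITS
table) are combined with :func:`merge_domains`, which converts each table to
per-sample relative abundance *before* concatenating rows, so that the merged
matrix encodes composition rather than sequencing depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RhizonetError",
    "FormatError",
    "AlignmentError",
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "read_metadata",
    "merge_domains",
]

#: Taxonomic ranks recognised by :class:`TaxonomyMap`, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_REL_TOL = 1e-9


class RhizonetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RhizonetError):
    """Malformed input table (duplicate ids, non-numeric cells, ragged rows)."""


class AlignmentError(RhizonetError):
    """Sample or OTU identifier sets do not line up across inputs."""


@dataclass
class OtuTable:
    """OTUs × samples abundance matrix with validated identifiers.

    Parameters
    ----------
    data
        DataFrame with OTU ids as the index and sample ids as columns.
        Values must be non-negative and finite.
    is_relative
        When True the table holds relative abundances: every non-zero sample
        column must sum to the same positive integer (1 for a normalized
        single-domain table, *k* for a *k*-domain merge produced by
        :func:`merge_domains`).
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU id(s): {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("OTU table values must be numeric")
        if values.size and (~np.isfinite(values)).any():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at OTU {idx[r]!r}, sample {cols[c]!r}"
            )
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at OTU {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.is_relative and values.size:
            sums = values.sum(axis=0)
            nonzero = sums[sums > _REL_TOL]
            if nonzero.size:
                target = round(float(nonzero[0]))
                if target < 1 or np.abs(nonzero - target).max() > 1e-6:
                    raise FormatError(
                        "relative-abundance columns must share a common "
                        f"integer sum; got sums {sorted(set(np.round(sums, 6)))}"
                    )

    # -- basic introspection -------------------------------------------------

    @property
    def otu_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        """Matrix view, shape (n_otus, n_samples)."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def otu_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def to_relative(self) -> "OtuTable":
        """Per-sample relative abundance; all-zero columns stay zero."""
        sums = self.data.sum(axis=0)
        safe = sums.replace(0, np.nan)
        rel = self.data.div(safe, axis=1).fillna(0.0)
        return OtuTable(rel, is_relative=True)

    def select_samples(self, sample_ids: Sequence) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise AlignmentError(f"unknown sample id(s): {missing}")
        return OtuTable(self.data.loc[:, list(sample_ids)].copy(), self.is_relative)

    def equals(self, other: "OtuTable", tol: float = _REL_TOL) -> bool:
        if self.otu_ids != other.otu_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.counts, other.counts
        if a.size == 0:
            return b.size == 0
        return bool(np.abs(a.astype(float) - b.astype(float)).max() <= tol)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "relative" if self.is_relative else "counts"
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples, {kind})"


@dataclass
class TaxonomyMap:
    """Mapping from OTU id to a ranked lineage (domain … genus).

    Lineages are stored as tuples of ≤6 rank names; unknown/empty ranks are
    empty strings. Missing OTUs are reported as ``"unclassified"`` by
    :meth:`get_rank`.
    """

    lineages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for otu, lin in self.lineages.items():
            lin = tuple(str(x) if x is not None else "" for x in lin)
            if len(lin) > len(RANKS):
                raise FormatError(
                    f"lineage for {otu!r} has {len(lin)} ranks (max {len(RANKS)})"
                )
            clean[otu] = lin
        self.lineages = clean

    def get_rank(self, otu_id, rank: str = "phylum") -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
        lin = self.lineages.get(otu_id)
        if lin is None:
            return "unclassified"
        i = RANKS.index(rank)
        if i >= len(lin) or not lin[i]:
            return "unclassified"
        return lin[i]

    def __contains__(self, otu_id) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class SampleMetadata:
    """Per-sample design factors (soil, plant, treatment, …).

    Wraps a DataFrame indexed by sample id; every factor column must be fully
    observed (no missing entries).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s) in metadata: {dupes}")
        if self.data.isna().any().any():
            col = self.data.columns[self.data.isna().any()][0]
            raise FormatError(f"missing values in metadata factor {col!r}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def factors(self) -> list:
        return self.data.columns.tolist()

    def factor(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown factor {name!r}; have {self.factors}")
        return self.data[name]

    def aligned_to(self, sample_ids: Sequence) -> "SampleMetadata":
        """Reorder strictly by sample id; error on any id missing."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise AlignmentError(f"metadata missing sample id(s): {missing}")
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


# -- I/O ---------------------------------------------------------------------


def read_otu_table(path, format: str = "tsv", is_relative: bool = False) -> OtuTable:
    """Read an OTU table from ``tsv`` or ``biom-json``.

    TSV dialect: first column OTU id, header row sample ids, numeric cells.
    Row/column order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"OTU table not found: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"non-numeric cell at OTU {df.index[r]!r}, "
                f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
            )
        if numeric.isna().any().any():
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise FormatError(
                f"missing cell (ragged row?) at OTU {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        vals = numeric.to_numpy()
        if vals.size and not is_relative and np.allclose(vals, np.round(vals)):
            numeric = numeric.round().astype(np.int64)
        return OtuTable(numeric, is_relative=is_relative)
    if format == "biom-json":
        return _read_biom_json(path, is_relative=is_relative)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom-json'")


def _read_biom_json(path: Path, is_relative: bool = False) -> OtuTable:
    """Minimal reader for the BIOM 1.0 JSON table layout."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [row["id"] for row in doc["rows"]]
        sample_ids = [col["id"] for col in doc["columns"]]
        n, m = doc["shape"]
        matrix_type = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a BIOM 1.0 JSON table: missing {exc}") from exc
    if len(otu_ids) != n or len(sample_ids) != m:
        raise FormatError("BIOM shape does not match rows/columns lists")
    mat = np.zeros((n, m), dtype=float)
    if matrix_type == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    elif matrix_type == "dense":
        mat[:] = np.asarray(data, dtype=float)
    else:
        raise FormatError(f"unknown BIOM matrix_type {matrix_type!r}")
    df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    if not is_relative and np.allclose(mat, np.round(mat)):
        df = df.round().astype(np.int64)
    return OtuTable(df, is_relative=is_relative)


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    """Write a table re-readable by :func:`read_otu_table`.

    Relative abundances are serialized with 17 significant digits so the
    read∘write round trip is exact to well below 1e-9.
    """
    path = Path(path)
    if format == "tsv":
        if table.is_relative:
            table.data.to_csv(path, sep="\t", float_format="%.17g")
        else:
            table.data.to_csv(path, sep="\t")
        return
    if format == "biom-json":
        vals = table.counts
        rows_idx, cols_idx = np.nonzero(vals)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "rhizonet",
            "matrix_type": "sparse",
            "matrix_element_type": "int" if not table.is_relative else "float",
            "shape": list(table.shape),
            "rows": [{"id": str(o), "metadata": None} for o in table.otu_ids],
            "columns": [{"id": str(s), "metadata": None} for s in table.sample_ids],
            "data": [
                [int(r), int(c), float(vals[r, c])]
                for r, c in zip(rows_idx.tolist(), cols_idx.tolist())
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom-json'")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV: otu_id followed by up to six rank columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"taxonomy table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate OTU id(s) in taxonomy: {dupes}")
    if df.shape[1] > len(RANKS):
        raise FormatError(
            f"taxonomy has {df.shape[1]} rank columns (max {len(RANKS)})"
        )
    return TaxonomyMap({otu: tuple(row) for otu, row in zip(df.index, df.to_numpy())})


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV: sample_id followed by factor columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(df)


# -- cross-domain merging ----------------------------------------------------


def merge_domains(tables: Sequence[OtuTable]) -> OtuTable:
    """Stack marker-gene tables over a shared sample set.

    Each input is independently converted to per-sample relative abundance,
    then rows are concatenated. The output therefore has per-sample column
    sum equal to the number of input tables — a constant that leaves any
    correlation computed across samples unchanged. Sample order follows the
    first table.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("merge_domains requires at least one table")
    ref = tables[0].sample_ids
    ref_set = set(ref)
    for i, t in enumerate(tables[1:], start=2):
        tset = set(t.sample_ids)
        if tset != ref_set:
            missing = sorted(ref_set - tset) + sorted(tset - ref_set)
            raise AlignmentError(
                f"table {i} sample set differs from table 1; mismatched: {missing}"
            )
    seen: set = set()
    for t in tables:
        overlap = seen.intersection(t.otu_ids)
        if overlap:
            raise FormatError(f"OTU id collision across domains: {sorted(overlap)[:5]}")
        seen.update(t.otu_ids)
    parts = [t.select_samples(ref).to_relative().data for t in tables]
    merged = pd.concat(parts, axis=0)
    return OtuTable(merged, is_relative=True)
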