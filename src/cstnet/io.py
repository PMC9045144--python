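"""Reading, writing and validation of abundance tables, metadata and networks.

The universal currency of the pipeline is the :class:`AbundanceTable`: a
samples x species matrix of relative abundances stored as fractions that sum
to one per sample.  Tables are sample-major (rows are samples); a transposed
input must be transposed explicitly by the caller, it is never guessed.
Species absent from a sample are explicit zeros, not missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "FormatError",
    "GROUP_LEVELS",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_network",
    "read_network",
]

#: Allowed levels of the mandatory ``group`` metadata column.
GROUP_LEVELS = ("athlete", "non_athlete")

ROW_SUM_TOL = 1e-6


class FormatError(ValueError):
    """A file violates the expected tabular layout (not just a bad value)."""


@dataclass
class AbundanceTable:
    """Samples x species relative-abundance matrix.

    Parameters
    ----------
    data :
        DataFrame with sample identifiers as the index and species names as
        columns.  Values are fractions; every row sums to 1 within ``1e-6``.

    Invariants are checked on construction: non-negative values, unique
    sample and species identifiers, unit row sums.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate species ids: {dups}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("abundance table contains missing values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative values")
        row_sums = values.sum(axis=1)
        bad = np.flatnonzero(np.abs(row_sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise ValueError(
                "rows do not sum to 1 within tolerance: "
                f"{[df.index[i] for i in bad[:5]]}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def subset(self, sample_ids: Sequence) -> "AbundanceTable":
        """Return a new table restricted to ``sample_ids`` (order preserved)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return AbundanceTable(normalize(self.data.loc[list(sample_ids)]))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "AbundanceTable":
        """Build a table from raw counts by dividing each row by its sum."""
        return cls(normalize(counts))


def normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its sum; reject all-zero rows.

    Idempotent on already-relative input: re-normalizing changes values by
    at most floating-point rounding.
    """
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values cannot be normalized")
    row_sums = values.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(f"zero-sum rows for samples: {[df.index[i] for i in zero]}")
    return pd.DataFrame(values / row_sums[:, None], index=df.index, columns=df.columns)


def read_abundance_table(path, input_kind: str = "relative") -> AbundanceTable:
    """Read a tab-separated abundance table.

    The first column holds sample identifiers and the header row species
    names.  ``input_kind='counts'`` divides each row by its row sum;
    ``'relative'`` input is renormalized as well (a no-op within rounding on
    tables that already sum to one), so the unit-row-sum invariant always
    holds downstream.
    """
    if input_kind not in ("counts", "relative"):
        raise ValueError(f"input_kind must be 'counts' or 'relative', got {input_kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no species columns found")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate species names")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance values") from exc
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    return AbundanceTable(normalize(values))


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table as TSV (sample ids in the first column)."""
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata: TSV with mandatory ``sample_id`` and ``group``.

    ``group`` is restricted to ``{athlete, non_athlete}``.  Extra columns
    (sport, study, sex, ...) are preserved as optional categoricals.
    Returns a DataFrame indexed by sample id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in metadata")
    unknown = sorted(set(df["group"]) - set(GROUP_LEVELS))
    if unknown:
        raise ValueError(
            f"unknown group level(s) {unknown}; allowed levels are {list(GROUP_LEVELS)}"
        )
    out = df.set_index("sample_id")
    for col in out.columns:
        out[col] = out[col].astype("category")
    return out


def align_metadata(table: AbundanceTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows in table order; every sample must have one row."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    return metadata.loc[table.sample_ids]


# -- network serialization -----------------------------------------------------

_EDGE_COLUMNS = ["taxon_a", "taxon_b", "tau", "p", "q", "sign"]


def write_network(network, path, format: str = "graphml") -> None:
    """Serialize a co-occurrence network.

    ``graphml`` carries node attributes (mean abundance, degree, module id)
    and edge attributes (tau, p, q, sign); ``edge_tsv`` writes the columns
    ``taxon_a, taxon_b, tau, p, q, sign`` (one line per edge, header always
    present, node-only information is not represented).
    """
    graph = getattr(network, "graph", network)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge_tsv":
        rows = [
            {"taxon_a": a, "taxon_b": b, "tau": d["tau"], "p": d["p"],
             "q": d["q"], "sign": d["sign"]}
            for a, b, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path)
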