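"""Readers and writers for the on-disk artifacts the pipeline touches.

Expression matrices travel as MatrixMarket ``.mtx`` (plus one-id-per-line
gene/cell TSVs) or as dense TSV; flow-cytometry event tables as CSV/TSV with
a header row; gene signatures as plain-text lists.  Every reader/writer pair
is a lossless round trip on valid inputs and never silently reorders rows or
columns.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its declared format."""


LAYER_TAGS = ("counts", "lognorm")
PARAM_KINDS = ("fluorescent", "scatter")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with per-cell phenotype labels.

    ``values`` is dense float64, genes on rows.  ``layer_tag`` declares
    whether the matrix holds raw counts (integer-valued, >= 0) or
    log-normalized expression.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_labels = [str(l) for l in self.cell_labels]
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self) -> None:
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"layer_tag must be one of {LAYER_TAGS}, got {self.layer_tag!r}")
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        ng, nc = self.values.shape
        if ng != len(self.gene_ids) or nc != len(self.cell_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(self.cell_labels) != nc:
            raise FormatError("cell_labels length does not match number of cells")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "cell id")
        if np.any(self.values < 0):
            raise FormatError("expression values must be non-negative")
        if self.layer_tag == "counts" and not np.allclose(self.values, np.round(self.values)):
            raise FormatError("counts layer must be integer-valued")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Row positions of the given genes; raises KeyError listing misses."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_labels=[self.cell_labels[i] for i in idx],
            layer_tag=self.layer_tag,
        )


@dataclass
class EventTable:
    """Flow-cytometry events x instrument parameters, with population labels.

    Each parameter carries a kind flag (``fluorescent`` parameters are
    log-transformed downstream; ``scatter`` stays linear).  ``cell_ids`` is
    present for index-sorted tables and absent for anonymous events.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    population: np.ndarray
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=object)
        self.validate()

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def fluorescent_params(self) -> list[str]:
        return [p for p in self.data.columns if self.kinds[p] == "fluorescent"]

    @property
    def scatter_params(self) -> list[str]:
        return [p for p in self.data.columns if self.kinds[p] == "scatter"]

    def validate(self) -> None:
        for p in self.data.columns:
            kind = self.kinds.get(p)
            if kind not in PARAM_KINDS:
                raise FormatError(f"parameter {p!r} has invalid kind flag {kind!r}")
        extra = set(self.kinds) - set(self.data.columns)
        if extra:
            raise FormatError(f"kind flags for unknown parameters: {sorted(extra)}")
        if len(self.population) != len(self.data):
            raise FormatError("population labels length does not match events")
        if self.cell_ids is not None:
            if len(self.cell_ids) != len(self.data):
                raise FormatError("cell_ids length does not match events")
            _check_unique(self.cell_ids, "cell id")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            bad = [c for c, dt in self.data.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise FormatError(f"non-numeric parameter columns: {bad}")

    def subset(self, mask_or_idx) -> "EventTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EventTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            kinds=dict(self.kinds),
            population=self.population[idx],
            cell_ids=None if self.cell_ids is None else [self.cell_ids[i] for i in idx],
        )


@dataclass
class SignatureList:
    """A named set of gene identifiers (opaque, case-sensitive strings)."""

    name: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = {str(g) for g in self.genes}
        if not self.genes:
            raise FormatError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# expression matrices


def _read_id_file(path) -> list[str]:
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [x for x in ids if x]


def read_expression(
    path_matrix,
    path_genes,
    path_cells,
    labels: Mapping[str, str] | Sequence[str] | None = None,
    layer_tag: str = "counts",
) -> ExpressionMatrix:
    """Read a genes x cells matrix from MatrixMarket ``.mtx`` or dense TSV.

    ``labels`` may be a per-cell sequence, a cell-id -> label mapping, or
    None (every cell labelled ``"unknown"``).
    """
    path_matrix = Path(path_matrix)
    gene_ids = _read_id_file(path_genes)
    cell_ids = _read_id_file(path_cells)
    _check_unique(gene_ids, "gene id")
    _check_unique(cell_ids, "cell id")

    text = path_matrix.read_text()
    if path_matrix.suffix == ".mtx" or text.startswith("%%MatrixMarket"):
        mat = spio.mmread(_io.StringIO(text))
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    else:
        values = pd.read_csv(_io.StringIO(text), sep="\t", header=None).to_numpy(dtype=float)
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix shape {values.shape} does not match id files "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
        )

    if labels is None:
        cell_labels = ["unknown"] * len(cell_ids)
    elif isinstance(labels, Mapping):
        missing = [c for c in cell_ids if c not in labels]
        if missing:
            raise FormatError(f"labels missing for cells: {missing[:5]}")
        cell_labels = [labels[c] for c in cell_ids]
    else:
        cell_labels = list(labels)
    return ExpressionMatrix(values, gene_ids, cell_ids, cell_labels, layer_tag)


def write_expression(matrix: ExpressionMatrix, path_matrix, path_genes, path_cells) -> None:
    """Write a matrix as MatrixMarket (``.mtx``) or dense TSV, by suffix."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        coo = sparse.coo_matrix(matrix.values)
        spio.mmwrite(str(path_matrix), coo, precision=12)
    else:
        pd.DataFrame(matrix.values).to_csv(
            path_matrix, sep="\t", header=False, index=False, float_format="%.12g"
        )
    Path(path_genes).write_text("".join(g + "\n" for g in matrix.gene_ids))
    Path(path_cells).write_text("".join(c + "\n" for c in matrix.cell_ids))


# ---------------------------------------------------------------------------
# flow-cytometry event tables


def read_events(path, schema: Mapping) -> EventTable:
    """Read a CSV/TSV event table.

    ``schema`` declares ``fluorescent`` and ``scatter`` parameter name lists,
    the ``population`` column, and optionally a ``cell_id`` column.  Rows are
    preserved in file order.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    fluor = list(schema.get("fluorescent", []))
    scatter = list(schema.get("scatter", []))
    pop_col = schema.get("population", "population")
    id_col = schema.get("cell_id")

    for col in fluor + scatter + [pop_col] + ([id_col] if id_col else []):
        if col not in df.columns:
            raise FormatError(f"schema names column {col!r} absent from header")
    params = fluor + scatter
    data = df[params].apply(pd.to_numeric, errors="coerce")
    if data.isna().any().any():
        bad = [c for c in params if data[c].isna().any()]
        raise FormatError(f"non-numeric values in parameter columns: {bad}")
    kinds = {p: "fluorescent" for p in fluor} | {p: "scatter" for p in scatter}
    return EventTable(
        data=data.reset_index(drop=True),
        kinds=kinds,
        population=df[pop_col].astype(str).to_numpy(),
        cell_ids=None if id_col is None else df[id_col].astype(str).tolist(),
    )


def write_events(table: EventTable, path) -> None:
    """Write an event table as CSV/TSV (suffix decides the separator)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    out = table.data.copy()
    out["population"] = table.population
    if table.cell_ids is not None:
        out.insert(0, "cell_id", table.cell_ids)
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")


def event_schema(table: EventTable) -> dict:
    """The schema dict that reads back a table written by :func:`write_events`."""
    schema = {
        "fluorescent": table.fluorescent_params,
        "scatter": table.scatter_params,
        "population": "population",
    }
    if table.cell_ids is not None:
        schema["cell_id"] = "cell_id"
    return schema


# ---------------------------------------------------------------------------
# gene signatures


def read_signature(path, name: str | None = None) -> SignatureList:
    """Read a one-gene-per-line signature; ``#`` starts a comment."""
    path = Path(path)
    genes = set()
    for ln in path.read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if ln:
            genes.add(ln)
    if not genes:
        raise FormatError(f"signature file {path} is empty after comment stripping")
    return SignatureList(name=name or path.stem, genes=genes)


def write_signature(sig: SignatureList, path) -> None:
    Path(path).write_text("".join(g + "\n" for g in sorted(sig.genes)))
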