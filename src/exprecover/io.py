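"""Expression-matrix container and text-format input/output.

Matrices are genes-in-rows, samples-in-columns.  Unobserved cells are held
as NaN inside :class:`ExpressionMatrix` and are never used in arithmetic;
the authoritative record of what is observed is the accompanying
:class:`~exprecover.masking.ObservationMask`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .masking import ObservationMask

_DEFAULT_NA = ("NA", "", "NaN", "null")


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with identifiers.

    Attributes
    ----------
    values : ndarray of float, shape (m, n)
        Expression values; NaN marks unobserved cells.
    gene_ids, sample_ids : list of str
        Row and column identifiers, unique within each axis.
    scale : {"raw", "log"}
        Whether values are on the measurement scale or log-transformed.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)
    scale: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError(f"matrix must have at least one row and column, got {m}x{n}")
        if self.gene_ids is None:
            self.gene_ids = [f"g{i}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{j}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dup[:5]}")
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        if self.scale == "log" and not np.all(np.isfinite(self.values) | np.isnan(self.values)):
            raise ValueError("log-scale matrix contains non-finite observed values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_matrix(path, dialect: str = "tsv", missing_token: str = "NA"):
    """Read a genes x samples matrix from TSV/CSV.

    The file must have a header row of sample ids and a first column of gene
    ids; cells are decimal numerals or ``missing_token`` (the tokens
    "NA", "", "NaN", "null" are always accepted as missing on read).

    Returns
    -------
    (ExpressionMatrix, ObservationMask)
        Missing cells are NaN in the matrix and absent from the mask.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    na = set(_DEFAULT_NA) | {missing_token}
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na),
                         keep_default_na=False, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"{path}: matrix has zero rows or zero columns")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell in na:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: line {i + 2}: cell ({gene_ids[i]}, {sample_ids[j]}) "
                    f"is not a number or {missing_token!r}: {cell!r}"
                ) from None
    x = ExpressionMatrix(values, gene_ids, sample_ids, scale="raw")
    mask = ObservationMask.from_bool(~np.isnan(values))
    return x, mask


def write_matrix(x: ExpressionMatrix, mask: ObservationMask, path,
                 dialect: str = "tsv", missing_token: str = "NA") -> None:
    """Write a matrix with unobserved cells as ``missing_token``.

    Observed cells are written with ``repr`` precision so a read/write
    round trip reproduces the values bit for bit.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    if mask.shape != x.shape:
        raise ValueError(f"mask shape {mask.shape} != matrix shape {x.shape}")
    obs = mask.to_bool()
    with open(path, "w") as fh:
        fh.write("gene_id" + sep + sep.join(x.sample_ids) + "\n")
        for i, gid in enumerate(x.gene_ids):
            cells = [
                repr(float(x.values[i, j])) if obs[i, j] else missing_token
                for j in range(x.shape[1])
            ]
            fh.write(gid + sep + sep.join(cells) + "\n")


def log_transform(x: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log_base(v + pseudocount) on every observed cell.

    Expression measurements are heavily right-skewed; values correlate far
    better after a log transform, which is why prediction runs on the log
    scale.  Unobserved (NaN) cells are untouched.
    """
    if x.scale != "raw":
        raise ValueError("matrix is already log-scale")
    v = x.values
    obs = ~np.isnan(v)
    shifted = v[obs] + pseudocount
    if np.any(shifted <= 0):
        ii, jj = np.nonzero(obs)
        bad = np.nonzero(shifted <= 0)[0][0]
        i, j = ii[bad], jj[bad]
        raise ValueError(
            f"cell ({x.gene_ids[i]}, {x.sample_ids[j]}) = {v[i, j]} is <= "
            f"-pseudocount ({-pseudocount}); cannot log-transform"
        )
    out = v.copy()
    out[obs] = np.log(shifted) / np.log(base)
    return replace(x, values=out, scale="log")


def inverse_log_transform(x: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0) -> ExpressionMatrix:
    """base**v - pseudocount on every cell; returns to the raw scale."""
    if x.scale != "log":
        raise ValueError("matrix is not log-scale")
    with np.errstate(over="raise"):
        try:
            out = np.power(float(base), x.values) - pseudocount
        except FloatingPointError as exc:
            raise OverflowError(f"inverse log transform overflowed: {exc}") from exc
    return replace(x, values=out, scale="raw")
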