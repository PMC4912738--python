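"""Observed-entry sets (Omega) and the projection onto them.

A completion problem is defined by the pair (matrix, mask): the mask records
which cells of the genes x samples matrix were actually measured
("checkpoints") and which are to be predicted.  The key derived quantity is
the observability O = |Omega| / (m*n), the fraction of entries known before
prediction.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import scipy.io
import scipy.sparse


class ObservationMask:
    """Index set Omega of observed cells of an m x n matrix.

    Internally stored as parallel 0-based (row, col) index arrays, kept
    sorted in row-major order so that identical masks compare equal
    regardless of construction order.

    Parameters
    ----------
    shape : tuple of int
        (m, n) with m, n >= 1.
    rows, cols : array-like of int
        Indices of the observed cells; duplicates are an error.
    seed : int, optional
        Seed recorded for provenance when the mask was randomly sampled.
    """

    def __init__(self, shape: tuple[int, int], rows, cols, seed: int | None = None):
        m, n = int(shape[0]), int(shape[1])
        if m < 1 or n < 1:
            raise ValueError(f"mask shape must be positive, got {(m, n)}")
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        if rows.shape != cols.shape or rows.ndim != 1:
            raise ValueError("rows and cols must be 1-D arrays of equal length")
        if rows.size:
            if rows.min() < 0 or rows.max() >= m or cols.min() < 0 or cols.max() >= n:
                raise ValueError("mask indices out of bounds for shape %r" % ((m, n),))
        flat = rows * n + cols
        if np.unique(flat).size != flat.size:
            raise ValueError("duplicate (row, col) pairs in mask")
        order = np.argsort(flat, kind="stable")
        self.shape: tuple[int, int] = (m, n)
        self.rows: np.ndarray = rows[order]
        self.cols: np.ndarray = cols[order]
        self.seed = seed

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return int(self.rows.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationMask):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.rows, other.rows)
            and np.array_equal(self.cols, other.cols)
        )

    def __repr__(self) -> str:
        return (
            f"ObservationMask(shape={self.shape}, observed={len(self)}, "
            f"observability={observability(self):.4g})"
        )

    @property
    def entries(self) -> set[tuple[int, int]]:
        """Omega as a Python set of (row, col) pairs."""
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def to_bool(self) -> np.ndarray:
        """Dense boolean indicator of Omega."""
        b = np.zeros(self.shape, dtype=bool)
        b[self.rows, self.cols] = True
        return b

    @classmethod
    def from_bool(cls, indicator: np.ndarray, seed: int | None = None) -> "ObservationMask":
        indicator = np.asarray(indicator, dtype=bool)
        rows, cols = np.nonzero(indicator)
        return cls(indicator.shape, rows, cols, seed=seed)

    @classmethod
    def full(cls, m: int, n: int) -> "ObservationMask":
        rows, cols = np.divmod(np.arange(m * n, dtype=np.intp), n)
        return cls((m, n), rows, cols)

    def complement(self) -> "ObservationMask":
        """Mask of the unobserved cells."""
        return ObservationMask.from_bool(~self.to_bool())

    def values_at(self, x: np.ndarray) -> np.ndarray:
        """The vector of entries of ``x`` on Omega (row-major order)."""
        x = np.asarray(x)
        if x.shape != self.shape:
            raise ValueError(f"shape mismatch: mask {self.shape}, matrix {x.shape}")
        return x[self.rows, self.cols]


def sample_mask(
    m: int,
    n: int,
    observability: float,
    seed: int,
    ensure_coverage: bool = False,
) -> ObservationMask:
    """Sample round(observability*m*n) distinct cells uniformly at random.

    Parameters
    ----------
    observability : float in (0, 1]
        Target fraction of observed cells.
    seed : int
        Seed for the generator; the same arguments always give the same mask.
    ensure_coverage : bool
        If True, guarantee at least one observation in every row and every
        column (the completion problem is ill-posed for fully unobserved
        rows/columns).  Requires a budget of at least max(m, n) cells.
    """
    if not (0.0 < observability <= 1.0):
        raise ValueError(f"observability must be in (0, 1], got {observability}")
    k = int(round(observability * m * n))
    if k < 1:
        raise ValueError("observability too small: zero cells would be observed")
    rng = np.random.default_rng(seed)
    if not ensure_coverage:
        flat = rng.choice(m * n, size=k, replace=False)
        rows, cols = np.divmod(flat.astype(np.intp), n)
        mask = ObservationMask((m, n), rows, cols, seed=seed)
        _warn_uncovered(mask)
        return mask

    if k < max(m, n):
        raise ValueError(
            f"coverage requires at least max(m, n)={max(m, n)} cells, budget is {k}"
        )
    # one random cell per row, then per still-empty column, then fill uniformly
    rows = list(range(m))
    cols = list(rng.integers(0, n, size=m))
    covered_cols = set(cols)
    for j in range(n):
        if j not in covered_cols:
            rows.append(int(rng.integers(0, m)))
            cols.append(j)
    chosen = set(zip(rows, cols))
    flat_pool = rng.permutation(m * n)
    for f in flat_pool:
        if len(chosen) >= k:
            break
        ij = (int(f) // n, int(f) % n)
        chosen.add(ij)
    rr, cc = zip(*sorted(chosen))
    return ObservationMask((m, n), np.array(rr), np.array(cc), seed=seed)


def _warn_uncovered(mask: ObservationMask) -> None:
    m, n = mask.shape
    row_seen = np.zeros(m, dtype=bool)
    col_seen = np.zeros(n, dtype=bool)
    row_seen[mask.rows] = True
    col_seen[mask.cols] = True
    n_rows, n_cols = int((~row_seen).sum()), int((~col_seen).sum())
    if n_rows or n_cols:
        warnings.warn(
            f"mask leaves {n_rows} rows and {n_cols} columns with no "
            "observations; those slices cannot be recovered meaningfully",
            stacklevel=3,
        )


def observability(mask: ObservationMask) -> float:
    """Fraction of cells observed, |Omega| / (m*n)."""
    m, n = mask.shape
    return len(mask) / (m * n)


def project(mask: ObservationMask, x: np.ndarray) -> np.ndarray:
    """Orthogonal projection P_Omega: keep x on Omega, zero elsewhere."""
    x = np.asarray(x, dtype=float)
    if x.shape != mask.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape}, matrix {x.shape}")
    out = np.zeros_like(x)
    out[mask.rows, mask.cols] = x[mask.rows, mask.cols]
    return out


def sample_count_lower_bound(m: int, r: int, C: float = 1.0) -> float:
    """Theoretical lower bound C * m^(6/5) * r * log(m) on |Omega|.

    Below this sample count, recovery of a rank-``r`` matrix with ``m``
    genes is not guaranteed by the underlying theory; callers compare it
    against ``len(mask)``.  Natural logarithm.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if r < 1:
        raise ValueError("r must be >= 1")
    if C <= 0:
        raise ValueError("C must be positive")
    return C * m ** 1.2 * r * np.log(m)


# ---------------------------------------------------------------------------
# mask file formats


def write_mask_mm(mask: ObservationMask, path) -> None:
    """Write Omega as a MatrixMarket coordinate *pattern* file (1-based)."""
    m, n = mask.shape
    coo = scipy.sparse.coo_matrix(
        (np.ones(len(mask), dtype=np.int8), (mask.rows, mask.cols)), shape=(m, n)
    )
    scipy.io.mmwrite(str(path), coo, field="pattern")


def read_mask_mm(path) -> ObservationMask:
    """Read a MatrixMarket coordinate file as an observation mask."""
    coo = scipy.io.mmread(str(path)).tocoo()
    return ObservationMask(coo.shape, coo.row, coo.col)


def write_mask_pairs(mask: ObservationMask, gene_ids: Iterable[str],
                     sample_ids: Iterable[str], path) -> None:
    """Write Omega as a two-column TSV of (gene_id, sample_id) pairs."""
    gene_ids = list(gene_ids)
    sample_ids = list(sample_ids)
    with open(path, "w") as fh:
        for i, j in zip(mask.rows, mask.cols):
            fh.write(f"{gene_ids[i]}\t{sample_ids[j]}\n")


def read_mask_pairs(path, gene_ids: Iterable[str], sample_ids: Iterable[str]) -> ObservationMask:
    """Read a two-column (gene_id, sample_id) TSV as an observation mask."""
    gi = {g: i for i, g in enumerate(gene_ids)}
    si = {s: j for j, s in enumerate(sample_ids)}
    rows, cols = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            g, s = parts
            if g not in gi:
                raise ValueError(f"{path}: line {lineno}: unknown gene id {g!r}")
            if s not in si:
                raise ValueError(f"{path}: line {lineno}: unknown sample id {s!r}")
            rows.append(gi[g])
            cols.append(si[s])
    return ObservationMask((len(gi), len(si)), np.array(rows, dtype=np.intp),
                           np.array(cols, dtype=np.intp))
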