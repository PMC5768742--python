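"""Sparse Hi-C contact matrices: loading, binning, ICE balancing and QC statistics.

A :class:`ContactMatrix` stores the upper triangle of a symmetric count
matrix over either a restriction-fragment axis or a fixed-width bin
axis, together with an optional per-row balancing weight (bias) and a
mask of rows with no coverage. Balanced values are
``raw[i, j] / (bias[i] * bias[j])``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp

from .genome import BinnedAxis, FragmentMap, GenomeLayout

__all__ = [
    "ContactMatrix",
    "QCReport",
    "load_contacts",
    "bin_matrix",
    "ice_normalize",
    "estimate_map_resolution",
    "replicate_correlation",
    "save_matrix",
    "load_matrix",
]


@dataclass
class ContactMatrix:
    """Upper-triangular sparse contact matrix over a genomic axis."""

    axis: FragmentMap | BinnedAxis
    counts: sp.csr_matrix  # upper triangle (i <= j)
    bias: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # True = no coverage
    converged: bool = True

    def __post_init__(self):
        self.counts = sp.triu(self.counts).tocsr()
        if self.mask is None:
            self.mask = np.asarray(self.row_totals() == 0)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def genome(self) -> GenomeLayout:
        return self.axis.genome

    def sym(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once); cached."""
        cached = getattr(self, "_sym_cache", None)
        if cached is None:
            u = self.counts
            d = sp.diags(u.diagonal())
            cached = (u + u.T - d).tocsr()
            self._sym_cache = cached
        return cached

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.sym().sum(axis=1)).ravel()

    def total(self) -> float:
        """Total stored contacts (each pair counted once)."""
        return float(self.counts.sum())

    def balanced_weights(self) -> np.ndarray:
        """1/bias with masked rows set to 0 (bias of 1 when unbalanced)."""
        if self.bias is None:
            w = np.ones(self.n)
        else:
            w = np.where(np.isfinite(self.bias) & (self.bias > 0), 1.0 / self.bias, 0.0)
        w[self.mask] = 0.0
        return w

    def balanced_dense(self, chrom: str | None = None) -> np.ndarray:
        """Dense symmetric balanced matrix (small instances only)."""
        s = self.axis.chrom_slice(chrom) if chrom else slice(None)
        w = self.balanced_weights()[s]
        m = self.sym()[s, s].toarray()
        return m * np.outer(w, w)

    def banded(self, chrom: str, max_span: int | None = None, balanced: bool = True):
        """Per-chromosome banded view ``B[i, d] = M[i, i + d]`` for d in 0..max_span."""
        s = self.axis.chrom_slice(chrom)
        n = s.stop - s.start
        if max_span is None or max_span > n - 1:
            max_span = n - 1
        sub = self.counts[s, s].tocoo()
        d = sub.col - sub.row
        keep = (d >= 0) & (d <= max_span)
        dtype = np.float32 if n * (max_span + 1) > 2_000_000 else np.float64
        B = np.zeros((n, max_span + 1), dtype=dtype)
        np.add.at(B, (sub.row[keep], d[keep]), sub.data[keep])
        if balanced:
            w = self.balanced_weights()[s].astype(dtype)
            for dd in range(max_span + 1):
                B[: n - dd, dd] *= w[: n - dd] * w[dd:]
        return B


class QCReport(NamedTuple):
    map_resolution: int
    map_resolution_qualified: bool
    replicate_correlation: float | None
    total_valid_pairs: float


def load_contacts(path, fragments: FragmentMap) -> ContactMatrix:
    """Load fragment-level contacts from a pairs-like or COO triplet text file.

    4 columns ``chrom1 pos1 chrom2 pos2`` are interpreted as one contact
    per line; 3 numeric columns ``i j count`` as fragment-index COO
    entries against ``fragments``. Header lines starting with '#' are
    ignored. Each pair is assigned to (fragment_i, fragment_j) with
    i <= j.
    """
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) == 4:
                    c1, p1, c2, p2 = parts[0], int(parts[1]), parts[2], int(parts[3])
                    i = int(fragments.locate_global(c1, p1))
                    j = int(fragments.locate_global(c2, p2))
                    v = 1.0
                elif len(parts) == 3:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                    if not (0 <= i < fragments.n and 0 <= j < fragments.n):
                        raise ValueError(f"fragment index out of range: {i}, {j}")
                else:
                    raise ValueError(f"expected 3 or 4 columns, got {len(parts)}")
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if i > j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
            vals.append(v)
    n = fragments.n
    counts = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ContactMatrix(fragments, counts)


def matrix_from_coo(axis, i, j, v) -> ContactMatrix:
    i = np.asarray(i)
    j = np.asarray(j)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    counts = sp.coo_matrix((np.asarray(v, float), (lo, hi)), shape=(axis.n, axis.n))
    return ContactMatrix(axis, counts.tocsr())


def bin_matrix(matrix: ContactMatrix, binsize: int) -> ContactMatrix:
    """Aggregate a fragment-axis matrix onto fixed bins (fragment -> bin of its midpoint).

    Total counts are conserved exactly. Bias is dropped (binned matrices
    are re-balanced if needed).
    """
    fm = matrix.axis
    if not isinstance(fm, FragmentMap):
        raise TypeError("bin_matrix expects a fragment-axis matrix")
    axis = BinnedAxis(fm.genome, int(binsize))
    binof = np.empty(fm.n, dtype=np.int64)
    for chrom in fm.genome.names:
        s = fm.chrom_slice(chrom)
        mids = fm.midpoints(chrom)
        binof[s] = np.minimum(mids // binsize, axis.n_chrom(chrom) - 1) + axis.offsets[chrom]
    coo = matrix.counts.tocoo()
    return matrix_from_coo(axis, binof[coo.row], binof[coo.col], coo.data)


def ice_normalize(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction (ICE): find per-row biases equalising balanced row sums.

    Rows with zero total counts are masked and excluded. Returns a new
    matrix sharing the counts with ``bias`` set (mean 1 over unmasked
    rows) and ``converged`` flagging whether the maximum relative
    row-sum deviation fell below ``tol`` within ``max_iter`` iterations.
    """
    S = matrix.sym()
    mask = np.asarray(matrix.row_totals() == 0)
    unmasked = ~mask
    b = np.ones(matrix.n)
    converged = False
    if unmasked.sum() == 0:
        converged = True
    else:
        for _ in range(max_iter):
            inv = np.where(unmasked, 1.0 / b, 0.0)
            s = S.dot(inv) * inv  # balanced row sums
            m = s[unmasked].mean()
            if m == 0:
                break
            dev = np.abs(s[unmasked] / m - 1.0).max()
            if dev < tol:
                converged = True
                break
            b[unmasked] *= np.sqrt(s[unmasked] / m)
        b[unmasked] /= b[unmasked].mean()
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (tol={tol})",
            RuntimeWarning,
            stacklevel=2,
        )
    bias = np.where(unmasked, b, np.nan)
    return replace(matrix, bias=bias, mask=mask, converged=converged)


class MapResolution(NamedTuple):
    binsize: int
    qualified: bool
    fractions: dict[int, float]


def estimate_map_resolution(
    matrix: ContactMatrix,
    candidate_binsizes: list[int],
    min_contacts: int = 1000,
    fraction: float = 0.8,
) -> MapResolution:
    """Smallest candidate bin size at which >= ``fraction`` of covered bins
    have >= ``min_contacts`` total contacts (Rao-style map resolution).

    Falls back to the largest candidate, flagged unqualified, when none
    passes.
    """
    candidates = sorted(int(b) for b in candidate_binsizes)
    fractions = {}
    for binsize in candidates:
        binned = matrix if (
            isinstance(matrix.axis, BinnedAxis) and matrix.axis.binsize == binsize
        ) else bin_matrix(matrix, binsize)
        totals = binned.row_totals()
        covered = totals > 0
        frac = float((totals >= min_contacts).sum() / covered.sum()) if covered.any() else 0.0
        fractions[binsize] = frac
        if frac >= fraction:
            return MapResolution(binsize, True, fractions)
    return MapResolution(candidates[-1], False, fractions)


def replicate_correlation(
    matA: ContactMatrix, matB: ContactMatrix, binsize: int = 20_000
) -> float:
    """Pearson correlation of two replicates over the union of non-zero
    upper-triangle entries after binning both to ``binsize``."""
    a = bin_matrix(matA, binsize) if isinstance(matA.axis, FragmentMap) else matA
    b = bin_matrix(matB, binsize) if isinstance(matB.axis, FragmentMap) else matB
    if a.n != b.n:
        raise ValueError("matrices must share the same axis")
    union = (a.counts + b.counts).tocoo()
    va = np.asarray(a.counts[union.row, union.col]).ravel()
    vb = np.asarray(b.counts[union.row, union.col]).ravel()
    return float(np.corrcoef(va, vb)[0, 1])


# -- persistence: COO text + JSON sidecar -------------------------------------


def save_matrix(matrix: ContactMatrix, coo_path, sidecar_path) -> None:
    coo = matrix.counts.tocoo()
    with open(coo_path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
    axis = matrix.axis
    meta = {
        "genome": list(axis.genome.chromosomes),
        "axis": "fragments" if isinstance(axis, FragmentMap) else "bins",
        "binsize": None if isinstance(axis, FragmentMap) else axis.binsize,
        "mask": np.flatnonzero(matrix.mask).tolist(),
        "bias": None if matrix.bias is None else [
            None if not np.isfinite(x) else float(x) for x in matrix.bias
        ],
        "converged": bool(matrix.converged),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh)


def load_matrix(coo_path, sidecar_path, fragments: FragmentMap | None = None) -> ContactMatrix:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    genome = GenomeLayout(tuple((c, int(n)) for c, n in meta["genome"]))
    if meta["axis"] == "fragments":
        if fragments is None:
            raise ValueError("fragment-axis matrix requires a FragmentMap")
        axis = fragments
    else:
        axis = BinnedAxis(genome, int(meta["binsize"]))
    data = np.loadtxt(coo_path, ndmin=2)
    if data.size == 0:
        counts = sp.csr_matrix((axis.n, axis.n))
    else:
        counts = sp.coo_matrix(
            (data[:, 2], (data[:, 0].astype(int), data[:, 1].astype(int))),
            shape=(axis.n, axis.n),
        ).tocsr()
    bias = None if meta["bias"] is None else np.array(
        [np.nan if x is None else x for x in meta["bias"]]
    )
    m = ContactMatrix(axis, counts, bias=bias, converged=meta["converged"])
    mask = np.zeros(axis.n, dtype=bool)
    mask[meta["mask"]] = True
    m.mask = mask
    return m
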