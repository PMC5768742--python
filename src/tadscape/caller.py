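"""Armatus-style dynamic-programming TAD annotation.

The quality of a candidate domain spanning bins ``[k, l]`` is the sum of
balanced contacts with both ends inside the interval, scaled by the
interval span: ``q(k, l) = S(k, l) / (l - k)**gamma``. The normalised
score ``q'(k, l) = q(k, l) - mu(l - k)`` subtracts the mean quality of
all intervals of the same span, so that only intervals denser than
average are rewarded. The optimal segmentation maximises the sum of
``max(q', 0)`` over chosen non-overlapping intervals, allowing
unassigned bins in between; intervals with non-positive normalised
score are never emitted.

The exponent gamma controls the favoured domain scale (larger gamma,
smaller domains). The default gamma of 0.9 targets fragment-resolution
TADs; chromosomes whose domain borders abut read deserts (runs of
zero-coverage bins) are re-annotated at a lower fallback gamma (0.6 by
default) because deserts can masquerade as borders.

Quality tables are stored banded (start x span) so that chromosomes
with tens of thousands of fragments stay tractable; ``max_domain_bins``
caps the span considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedAxis, FragmentMap
from .matrix import ContactMatrix

__all__ = [
    "CallerConfig",
    "QualityTable",
    "Domain",
    "DomainSet",
    "BoundarySet",
    "domain_quality",
    "optimal_segmentation",
    "call_domains_dp",
    "call_domains_consensus",
    "readdesert_fallback",
    "boundary_centers",
    "contiguity_fraction",
    "nest_domains",
    "domain_size_stats",
    "read_domains",
    "write_domains",
]


@dataclass(frozen=True)
class CallerConfig:
    gamma: float = 0.9
    gamma_fallback: float = 0.6
    gamma_max: float = 2.0
    gamma_step: float = 0.1
    min_domain_bins: int = 2
    max_domain_bins: int | None = None
    desert_min: int = 3  # consecutive masked bins that count as a read desert
    level: str = "TAD"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.gamma_step <= 0:
            raise ValueError("gamma_step must be positive")
        if self.min_domain_bins < 2:
            raise ValueError("min_domain_bins must be >= 2")


@dataclass
class QualityTable:
    """Banded table of scaled interval densities.

    ``q[k, d]`` is the quality of the interval ``[k, k + d]`` (valid for
    ``d >= 1`` and ``k + d < n``); ``mu[d]`` is the exact mean of
    ``q[:, d]`` over all valid starts.
    """

    q: np.ndarray  # (n, max_span + 1); column 0 unused
    mu: np.ndarray  # (max_span + 1,)
    gamma: float
    n: int

    @property
    def max_span(self) -> int:
        return self.q.shape[1] - 1

    def qprime(self, k: int, l: int) -> float:
        d = l - k
        return float(self.q[k, d] - self.mu[d])


def _as_banded(mat, max_span=None, mask=None):
    """Accept a dense symmetric array or a banded (n, w) array marked by a flag."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D array")
    n = mat.shape[0]
    if mat.shape[0] == mat.shape[1] and np.allclose(mat, mat.T):
        w = n - 1 if max_span is None else min(max_span, n - 1)
        B = np.zeros((n, w + 1))
        for d in range(w + 1):
            B[: n - d, d] = np.diagonal(mat, d)
    else:  # already banded; not modified unless a mask is applied
        B = mat
        if max_span is not None and max_span + 1 < B.shape[1]:
            B = B[:, : max_span + 1]
    if mask is not None:
        B = B.copy()
        mask = np.asarray(mask, dtype=bool)
        w = B.shape[1] - 1
        for d in range(w + 1):
            m = mask[: n - d] | mask[d:]
            B[: n - d, d] = np.where(m, 0.0, B[: n - d, d])
    return B


def domain_quality(mat, gamma: float, max_span: int | None = None, mask=None) -> QualityTable:
    """Compute the banded quality table q and its per-span means mu.

    ``mat`` may be a dense symmetric matrix (small instances) or a
    banded array ``B[i, d] = M[i, i + d]``. Masked rows contribute zero.
    """
    B = _as_banded(mat, max_span=max_span, mask=mask)
    n, w1 = B.shape
    dtype = B.dtype
    # R[j, d] = sum_{e=0..d} B[j-e, e]  (partial column sums of the upper triangle)
    R = np.zeros_like(B)
    R[:, 0] = B[:, 0]
    for d in range(1, w1):
        R[d:, d] = R[d:, d - 1] + B[: n - d, d]
    # S[k, d] = sum of M over the interval [k, k+d] upper triangle
    S = np.zeros_like(B)
    S[:, 0] = B[:, 0]
    for d in range(1, w1):
        S[: n - d, d] = S[: n - d, d - 1] + R[d:, d]
        S[n - d :, d] = np.nan
    del R
    q = S
    mu = np.full(w1, np.nan, dtype=dtype)
    spans = np.arange(1, w1, dtype=dtype)
    for d in range(1, w1):
        q[: n - d, d] /= spans[d - 1] ** dtype.type(gamma)
        mu[d] = q[: n - d, d].mean()
    q[:, 0] = np.nan
    mu[0] = np.nan
    return QualityTable(q=q, mu=mu, gamma=float(gamma), n=n)


def optimal_segmentation(qt: QualityTable, min_domain_bins: int = 2):
    """Exact DP over the normalised quality table.

    Returns a list of ``(start_bin, end_bin_inclusive, score)`` maximising
    the total of ``max(q', 0)`` over non-overlapping intervals; intervals
    with ``q' <= 0`` are never emitted. Ties prefer fewer domains, then
    leftmost starts.
    """
    n, w1 = qt.n, qt.q.shape[1]
    dmin = min_domain_bins - 1
    if n < min_domain_bins:
        return []
    # gainT[l, d] = max(q'(l-d, l), 0), indexed by interval end
    gain = np.maximum(qt.q - qt.mu[None, :], 0.0)
    gainT = np.zeros_like(gain)
    for d in range(1, w1):
        gainT[d:, d] = gain[: n - d, d]
    del gain
    dp = np.zeros(n + 1)
    choice = np.full(n + 1, -1, dtype=np.int64)  # span d of domain ending at bin p-1
    for p in range(min_domain_bins, n + 1):
        l = p - 1
        dmax = min(w1 - 1, l)
        row = gainT[l, dmin : dmax + 1]
        ks = dp[l - dmax : l - dmin + 1][::-1]  # dp[l - d] for d ascending
        vals = row + ks
        j = int(len(vals) - 1 - np.argmax(vals[::-1]))  # largest d on ties
        best = vals[j]
        prev = dp[p - 1]
        if best > prev and gainT[l, dmin + j] > 0:
            dp[p] = best
            choice[p] = dmin + j
        else:
            dp[p] = prev
    # traceback
    out = []
    p = n
    while p > 0:
        d = choice[p]
        if d < 0:
            p -= 1
            continue
        l = p - 1
        k = l - d
        out.append((k, l, float(gainT[l, d])))
        p = k
    out.reverse()
    return out


@dataclass(frozen=True)
class Domain:
    chrom: str
    start_bin: int
    end_bin: int  # inclusive
    start_bp: int
    end_bp: int
    score: float
    gamma_used: float

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class DomainSet:
    """Sorted, non-overlapping annotated domains at one level (TAD or super-TAD)."""

    level: str
    domains: list[Domain]
    axis: FragmentMap | BinnedAxis | None = None

    def __post_init__(self):
        self.domains = sorted(self.domains, key=lambda d: (d.chrom, d.start_bp))
        by_chrom = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            for a, b in zip(ds, ds[1:]):
                if b.start_bp < a.end_bp:
                    raise ValueError(f"{chrom}: overlapping domains at {b.start_bp}")

    def __len__(self):
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)

    def per_chrom(self) -> dict[str, list[Domain]]:
        out = {}
        for d in self.domains:
            out.setdefault(d.chrom, []).append(d)
        return out

    def sizes(self) -> np.ndarray:
        return np.array([d.size_bp for d in self.domains])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": d.chrom,
                    "start": d.start_bp,
                    "end": d.end_bp,
                    "name": f"{self.level}:{i}",
                    "score": d.score,
                    "start_bin": d.start_bin,
                    "end_bin": d.end_bin,
                    "gamma_used": d.gamma_used,
                }
                for i, d in enumerate(self.domains)
            ]
        )


@dataclass
class BoundarySet:
    """One center per adjacent-domain junction: midpoint of upstream end and downstream start."""

    centers: list[tuple[str, int]]

    def __len__(self):
        return len(self.centers)

    def per_chrom(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, pos in self.centers:
            out.setdefault(chrom, []).append(pos)
        return {c: np.asarray(sorted(p), dtype=np.int64) for c, p in out.items()}


def _call_chrom(matrix: ContactMatrix, chrom: str, gamma: float, config: CallerConfig):
    axis = matrix.axis
    s = axis.chrom_slice(chrom)
    n = s.stop - s.start
    if n < config.min_domain_bins:
        return []
    B = matrix.banded(chrom, max_span=config.max_domain_bins, balanced=True)
    qt = domain_quality(B, gamma)
    segs = optimal_segmentation(qt, config.min_domain_bins)
    out = []
    for k, l, score in segs:
        out.append(
            Domain(
                chrom=chrom,
                start_bin=k,
                end_bin=l,
                start_bp=axis.bin_start(chrom, k),
                end_bp=axis.bin_end(chrom, l),
                score=score,
                gamma_used=gamma,
            )
        )
    return out


def call_domains_dp(matrix: ContactMatrix, config: CallerConfig | None = None) -> DomainSet:
    """Optimal single-gamma segmentation of every chromosome."""
    config = config or CallerConfig()
    domains = []
    for chrom in matrix.genome.names:
        domains.extend(_call_chrom(matrix, chrom, config.gamma, config))
    return DomainSet(config.level, domains, axis=matrix.axis)


def call_domains_consensus(matrix: ContactMatrix, config: CallerConfig | None = None) -> DomainSet:
    """Multi-gamma consensus: sweep gamma from 0 to gamma_max in gamma_step
    increments and keep domains whose both edges appear in at least half of
    the sweep's optimal solutions."""
    config = config or CallerConfig()
    gammas = np.arange(0.0, config.gamma_max + 1e-9, config.gamma_step)
    solutions = []
    for g in gammas:
        ds = []
        for chrom in matrix.genome.names:
            ds.extend(_call_chrom(matrix, chrom, float(g), config))
        solutions.append(ds)
    need = int(np.ceil(len(solutions) / 2))
    edge_counts: dict[tuple[str, int, str], int] = {}
    for ds in solutions:
        for d in ds:
            edge_counts[(d.chrom, d.start_bin, "s")] = (
                edge_counts.get((d.chrom, d.start_bin, "s"), 0) + 1
            )
            edge_counts[(d.chrom, d.end_bin, "e")] = (
                edge_counts.get((d.chrom, d.end_bin, "e"), 0) + 1
            )
    base = call_domains_dp(matrix, config)
    kept = [
        d
        for d in base
        if edge_counts.get((d.chrom, d.start_bin, "s"), 0) >= need
        and edge_counts.get((d.chrom, d.end_bin, "e"), 0) >= need
    ]
    return DomainSet(config.level, kept, axis=matrix.axis)


def _masked_runs(mask: np.ndarray, min_len: int):
    """(start, stop) half-open runs of True of length >= min_len."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_len]


def readdesert_fallback(
    matrix: ContactMatrix, domains: DomainSet, config: CallerConfig | None = None
) -> tuple[DomainSet, list[tuple[str, int, int]]]:
    """Re-annotate chromosomes whose domain borders abut read deserts.

    A trigger is a run of at least ``desert_min`` consecutive masked bins
    with a domain edge within one bin of the run. Triggered chromosomes
    are re-segmented at ``gamma_fallback``; other chromosomes keep the
    original annotation. Returns the merged set and the triggered runs.
    """
    config = config or CallerConfig()
    triggered: list[tuple[str, int, int]] = []
    per_chrom = domains.per_chrom()
    out = []
    for chrom in matrix.genome.names:
        s = matrix.axis.chrom_slice(chrom)
        mask = matrix.mask[s]
        runs = _masked_runs(mask, config.desert_min)
        ds = per_chrom.get(chrom, [])
        edges = sorted({d.start_bin for d in ds} | {d.end_bin for d in ds})
        hit = False
        for a, b in runs:
            # edge within one bin of the run [a, b)
            for e in edges:
                if a - 1 <= e <= b:
                    hit = True
                    triggered.append((chrom, int(a), int(b)))
                    break
        if hit and ds:
            out.extend(_call_chrom(matrix, chrom, config.gamma_fallback, config))
        else:
            out.extend(ds)
    return DomainSet(domains.level, out, axis=domains.axis), triggered


def boundary_centers(domains: DomainSet) -> BoundarySet:
    centers = []
    for chrom, ds in domains.per_chrom().items():
        for up, down in zip(ds, ds[1:]):
            centers.append((chrom, (up.end_bp + down.start_bp) // 2))
    return BoundarySet(centers)


def contiguity_fraction(domains: DomainSet, fragments: FragmentMap):
    """Fraction of adjacent-domain junctions whose flanking domains end and
    start on the same or adjacent restriction fragments (no intervening
    fragment). Also returns the per-junction table."""
    rows = []
    for chrom, ds in domains.per_chrom().items():
        for up, down in zip(ds, ds[1:]):
            gap = down.start_bin - up.end_bin - 1
            rows.append(
                {
                    "chrom": chrom,
                    "up_end_bin": up.end_bin,
                    "down_start_bin": down.start_bin,
                    "gap_fragments": gap,
                    "same_fragment": gap <= 0,
                }
            )
    table = pd.DataFrame(rows)
    frac = float(table["same_fragment"].mean()) if len(table) else float("nan")
    return frac, table


@dataclass
class NestingResult:
    assignment: pd.DataFrame  # per TAD: region ('super-TAD'|'inter-super-TAD'|None), region_index
    counts_super: pd.Series  # TADs per super-TAD
    counts_inter: pd.Series  # TADs per inter-super-TAD


def _inter_regions(supertads: DomainSet, genome) -> list[tuple[str, int, int]]:
    """Regions between (and flanking) super-TADs, per chromosome."""
    out = []
    per = supertads.per_chrom()
    for chrom, length in genome.chromosomes:
        prev = 0
        for d in per.get(chrom, []):
            if d.start_bp > prev:
                out.append((chrom, prev, d.start_bp))
            prev = d.end_bp
        if prev < length:
            out.append((chrom, prev, length))
    return out


def nest_domains(
    tads: DomainSet, supertads: DomainSet, inclusion: float = 0.75
) -> NestingResult:
    """Assign each TAD to the super-TAD or inter-super-TAD region covering at
    least ``inclusion`` of its length (75% of the TAD length by default); otherwise
    leave it unassigned."""
    genome = (tads.axis or supertads.axis).genome
    supers = list(supertads)
    inters = _inter_regions(supertads, genome)
    rows = []
    for ti, t in enumerate(tads):
        need = inclusion * t.size_bp
        region, ridx = None, -1
        for si, sdom in enumerate(supers):
            if sdom.chrom != t.chrom:
                continue
            ov = min(t.end_bp, sdom.end_bp) - max(t.start_bp, sdom.start_bp)
            if ov >= need:
                region, ridx = "super-TAD", si
                break
        if region is None:
            for gi, (chrom, a, b) in enumerate(inters):
                if chrom != t.chrom:
                    continue
                ov = min(t.end_bp, b) - max(t.start_bp, a)
                if ov >= need:
                    region, ridx = "inter-super-TAD", gi
                    break
        rows.append(
            {"tad": ti, "chrom": t.chrom, "region": region, "region_index": ridx}
        )
    assignment = pd.DataFrame(rows)
    cs = assignment[assignment["region"] == "super-TAD"]["region_index"].value_counts()
    ci = assignment[assignment["region"] == "inter-super-TAD"]["region_index"].value_counts()
    return NestingResult(assignment, cs.sort_index(), ci.sort_index())


def domain_size_stats(domains: DomainSet, total_bp: int | None = None) -> dict:
    sizes = domains.sizes()
    if total_bp is None and domains.axis is not None:
        total_bp = domains.axis.genome.total_length
    out = {
        "n_domains": int(len(domains)),
        "median_bp": float(np.median(sizes)) if len(sizes) else float("nan"),
        "q25_bp": float(np.percentile(sizes, 25)) if len(sizes) else float("nan"),
        "q75_bp": float(np.percentile(sizes, 75)) if len(sizes) else float("nan"),
        "min_bp": float(sizes.min()) if len(sizes) else float("nan"),
        "max_bp": float(sizes.max()) if len(sizes) else float("nan"),
        "covered_bp": float(sizes.sum()),
    }
    if total_bp:
        out["coverage"] = float(sizes.sum() / total_bp)
    return out


def write_domains(domains: DomainSet, path) -> None:
    """BED: chrom, start, end, name=level:index, score, strand '.', gamma_used."""
    df = domains.to_frame()
    df["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand", "gamma_used"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_domains(path, axis=None, level: str | None = None) -> DomainSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand", "gamma_used"],
        dtype={"chrom": str},
    )
    if level is None:
        level = str(df["name"].iloc[0]).split(":")[0] if len(df) else "TAD"
    domains = []
    for _, r in df.iterrows():
        if axis is not None and isinstance(axis, FragmentMap):
            sb = int(axis.locate(r["chrom"], r["start"]))
            eb = int(axis.locate(r["chrom"], r["end"] - 1))
        elif axis is not None:
            sb = int(r["start"] // axis.binsize)
            eb = int((r["end"] - 1) // axis.binsize)
        else:
            sb = eb = -1
        domains.append(
            Domain(
                chrom=str(r["chrom"]),
                start_bin=sb,
                end_bin=eb,
                start_bp=int(r["start"]),
                end_bp=int(r["end"]),
                score=float(r["score"]),
                gamma_used=float(r["gamma_used"]),
            )
        )
    return DomainSet(level, domains, axis=axis)
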