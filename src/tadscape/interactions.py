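"""Distance-decay expectation and TAD-level interaction metrics.

The expectation is the mean balanced contact over all unmasked fragment
pairs at the same genomic separation (fragment midpoint distance),
binned in 200 bp windows. Dividing an observed contact by the
expectation at its separation removes the polymer distance-decay
background; averaging those ratios over all fragment pairs spanning two
TADs gives the distance-normalised TAD-TAD enrichment. The mean
balanced contact over all intra-TAD fragment pairs ("condensation") is
the compaction proxy, compared only among TADs of similar size
(5-20 kb by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .caller import Domain, DomainSet, NestingResult
from .genome import FragmentMap
from .matrix import ContactMatrix

__all__ = [
    "ExpectedByDistance",
    "expected_by_distance",
    "expectation_matrix",
    "condensation",
    "pair_enrichment",
    "tad_pair_enrichments",
    "neighbor_type_summary",
    "supertad_contact_contrast",
    "condensation_type_test",
]

TYPE_LETTER = {"active": "A", "inactive": "I", "polycomb": "P", "undetermined": "U"}


@dataclass
class ExpectedByDistance:
    """Per-chromosome mean balanced contact by separation bin (fixed width)."""

    binwidth: int
    means: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]

    def lookup(self, chrom: str, separations) -> np.ndarray:
        """Expected contact at each separation; NaN for empty/uncovered bins."""
        sep = np.asarray(separations, dtype=np.int64)
        m = self.means[chrom]
        idx = sep // self.binwidth
        out = np.full(sep.shape, np.nan)
        ok = (idx >= 0) & (idx < m.size)
        out[ok] = m[idx[ok]]
        return out


def expected_by_distance(
    matrix: ContactMatrix,
    binwidth: int = 200,
    max_dist: int | None = None,
) -> ExpectedByDistance:
    """Mean balanced contact over all unmasked fragment pairs per separation
    bin, computed per chromosome. Pairs involving masked fragments are
    excluded from both numerator and denominator; empty bins are NaN."""
    axis = matrix.axis
    means, counts = {}, {}
    for chrom in matrix.genome.names:
        s = axis.chrom_slice(chrom)
        n = s.stop - s.start
        mids = axis.midpoints(chrom)
        unmasked = ~matrix.mask[s]
        if max_dist is None:
            span = n - 1
        else:  # largest d with any pair (i, i+d) within max_dist
            reach = np.searchsorted(mids, mids + max_dist, side="right") - np.arange(n) - 1
            span = min(n - 1, int(reach.max())) if n > 1 else 0
        B = matrix.banded(chrom, max_span=span, balanced=True)
        max_sep = int(mids[-1] - mids[0]) if n > 1 else 0
        nbins = max_sep // binwidth + 1
        sums = np.zeros(nbins)
        npairs = np.zeros(nbins)
        for d in range(1, B.shape[1]):
            sep = mids[d:] - mids[: n - d]
            valid = unmasked[: n - d] & unmasked[d:]
            if max_dist is not None:
                valid &= sep <= max_dist
            if not valid.any():
                continue
            idx = (sep[valid] // binwidth).astype(np.int64)
            sums += np.bincount(idx, weights=B[: n - d, d][valid], minlength=nbins)
            npairs += np.bincount(idx, minlength=nbins)
        with np.errstate(invalid="ignore", divide="ignore"):
            means[chrom] = np.where(npairs > 0, sums / npairs, np.nan)
        counts[chrom] = npairs
    return ExpectedByDistance(binwidth, means, counts)


def expectation_matrix(
    expected: ExpectedByDistance, fragments: FragmentMap, max_dist: int
) -> ContactMatrix:
    """Deterministic matrix whose every entry equals the distance expectation
    at the fragment pair's separation (a null for normalisation checks)."""
    rows, cols, vals = [], [], []
    for chrom in fragments.genome.names:
        o = fragments.offsets[chrom]
        n = fragments.n_chrom(chrom)
        mids = fragments.midpoints(chrom)
        reach = np.searchsorted(mids, mids + max_dist, side="right") - np.arange(n) - 1
        span = min(n - 1, int(reach.max())) if n > 1 else 0
        for d in range(1, span + 1):
            sep = mids[d:] - mids[: n - d]
            keep = sep <= max_dist
            e = expected.lookup(chrom, sep[keep])
            ok = np.isfinite(e) & (e > 0)
            i = np.flatnonzero(keep)[ok]
            rows.append(i + o)
            cols.append(i + d + o)
            vals.append(e[ok])
    n = fragments.n
    counts = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return ContactMatrix(fragments, counts)


def _balanced_block(matrix: ContactMatrix, rows: slice, cols: slice) -> np.ndarray:
    w = matrix.balanced_weights()
    block = matrix.sym()[rows, cols].toarray()
    return block * np.outer(w[rows], w[cols])


def condensation(
    matrix: ContactMatrix,
    domains: DomainSet,
    size_range: tuple[int, int] = (5000, 20000),
) -> pd.DataFrame:
    """Mean balanced contact over all intra-TAD fragment pairs, per TAD.

    Fragments with no ligation products (masked rows) are excluded; the
    ``included`` flag marks TADs inside the size-matched comparison
    window (5-20 kb by default)."""
    axis = matrix.axis
    rows = []
    for ti, d in enumerate(domains):
        o = axis.chrom_slice(d.chrom).start
        sl = slice(o + d.start_bin, o + d.end_bin + 1)
        keep = ~matrix.mask[sl]
        k = int(keep.sum())
        n_pairs = k * (k - 1) // 2
        if n_pairs > 0:
            block = _balanced_block(matrix, sl, sl)[keep][:, keep]
            mean = float(np.triu(block, k=1).sum() / n_pairs)
        else:
            mean = float("nan")
        rows.append(
            {
                "tad": ti,
                "chrom": d.chrom,
                "size_bp": d.size_bp,
                "condensation": mean,
                "n_pairs": n_pairs,
                "included": size_range[0] <= d.size_bp <= size_range[1],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairEnrichment:
    ratio: float
    n_pairs: int
    n_skipped: int


def pair_enrichment(
    matrix: ContactMatrix, domA: Domain, domB: Domain, expected: ExpectedByDistance
) -> PairEnrichment:
    """Mean of observed/expected over all fragment pairs spanning two disjoint
    TADs on the same chromosome. Pairs with undefined expectation or a
    masked fragment are skipped and counted."""
    if domA.chrom != domB.chrom:
        raise ValueError("domains must be on the same chromosome")
    if not (domA.end_bin < domB.start_bin or domB.end_bin < domA.start_bin):
        raise ValueError("domains must be disjoint")
    axis = matrix.axis
    chrom = domA.chrom
    o = axis.chrom_slice(chrom).start
    sa = slice(o + domA.start_bin, o + domA.end_bin + 1)
    sb = slice(o + domB.start_bin, o + domB.end_bin + 1)
    obs = _balanced_block(matrix, sa, sb)
    mids = axis.midpoints(chrom)
    ma = mids[domA.start_bin : domA.end_bin + 1]
    mb = mids[domB.start_bin : domB.end_bin + 1]
    sep = np.abs(mb[None, :] - ma[:, None])
    exp = expected.lookup(chrom, sep)
    keepA = ~matrix.mask[sa]
    keepB = ~matrix.mask[sb]
    valid = np.isfinite(exp) & (exp > 0) & np.outer(keepA, keepB)
    total = obs.size
    if valid.sum() == 0:
        return PairEnrichment(float("nan"), 0, total)
    ratio = float((obs[valid] / exp[valid]).mean())
    return PairEnrichment(ratio, int(valid.sum()), int(total - valid.sum()))


def tad_pair_enrichments(
    matrix: ContactMatrix,
    domains: DomainSet,
    expected: ExpectedByDistance,
    mode: str = "adjacent",
) -> pd.DataFrame:
    """Distance-normalised enrichment for TAD pairs (adjacent pairs by default)."""
    if mode != "adjacent":
        raise ValueError("only 'adjacent' mode is implemented")
    per = domains.per_chrom()
    index_of = {id(d): i for i, d in enumerate(domains)}
    rows = []
    for chrom, ds in per.items():
        for a, b in zip(ds, ds[1:]):
            pe = pair_enrichment(matrix, a, b, expected)
            rows.append(
                {
                    "tad_i": index_of[id(a)],
                    "tad_j": index_of[id(b)],
                    "chrom": chrom,
                    "ratio": pe.ratio,
                    "n_pairs": pe.n_pairs,
                    "n_skipped": pe.n_skipped,
                }
            )
    return pd.DataFrame(rows)


def neighbor_type_summary(
    enrichments: pd.DataFrame,
    classes: pd.DataFrame,
    n_boot: int = 200,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mean enrichment ratio per TAD type pair (A-A, A-I, I-I, ...) over
    adjacent TAD pairs, with seeded bootstrap intervals."""
    letters = classes["major_type"].map(TYPE_LETTER)
    rng = np.random.default_rng(seed)
    rows = []
    lab = [
        "-".join(sorted((letters.iloc[i], letters.iloc[j])))
        for i, j in zip(enrichments["tad_i"], enrichments["tad_j"])
    ]
    df = enrichments.assign(type_pair=lab).dropna(subset=["ratio"])
    for pair, sub in df.groupby("type_pair"):
        r = sub["ratio"].to_numpy()
        boots = rng.choice(r, size=(n_boot, r.size), replace=True).mean(axis=1)
        rows.append(
            {
                "type_pair": pair,
                "mean_ratio": float(r.mean()),
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
                "n": int(r.size),
            }
        )
    return pd.DataFrame(rows).set_index("type_pair")


@dataclass
class SupertadContrast:
    within_mean: float
    across_mean: float
    ratio: float
    n_within: int
    n_across: int


def supertad_contact_contrast(
    enrichments: pd.DataFrame, nesting: NestingResult
) -> SupertadContrast | None:
    """Mean enrichment for TAD pairs inside one super-TAD versus pairs whose
    members belong to different regions (spanning an inter-super-TAD)."""
    assign = nesting.assignment.set_index("tad")
    region = assign["region"]
    ridx = assign["region_index"]
    within, across = [], []
    for _, r in enrichments.dropna(subset=["ratio"]).iterrows():
        i, j = int(r["tad_i"]), int(r["tad_j"])
        if region.get(i) == "super-TAD" and region.get(j) == "super-TAD" and ridx.get(i) == ridx.get(j):
            within.append(r["ratio"])
        elif region.get(i) is not None and region.get(j) is not None and (
            region.get(i) != region.get(j) or ridx.get(i) != ridx.get(j)
        ):
            across.append(r["ratio"])
    if not within:
        return None
    wm = float(np.mean(within))
    am = float(np.mean(across)) if across else float("nan")
    return SupertadContrast(wm, am, wm / am if across else float("nan"), len(within), len(across))


def condensation_type_test(
    cond: pd.DataFrame,
    classes: pd.DataFrame,
    type_a: str = "active",
    type_b: str = "inactive",
    n_perm: int = 1000,
    seed: int | None = 0,
) -> float:
    """Two-sided permutation test (over TAD labels) of the mean condensation
    difference between two TAD types, within the size-matched set."""
    df = cond[cond["included"]].join(classes["major_type"], on="tad")
    df = df[df["major_type"].isin([type_a, type_b])].dropna(subset=["condensation"])
    x = df.loc[df["major_type"] == type_a, "condensation"].to_numpy()
    y = df.loc[df["major_type"] == type_b, "condensation"].to_numpy()
    if x.size == 0 or y.size == 0:
        return float("nan")
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = abs(pooled[: x.size].mean() - pooled[x.size :].mean())
        if diff >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
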