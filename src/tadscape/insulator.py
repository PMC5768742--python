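"""Insulator-protein enrichment at TAD boundaries.

Occupancy profiles are averaged in fixed windows (80 bp by default)
across a flank (±4 kb by default) around every boundary center, and
compared with the same profile computed from randomly re-positioned
centers. Peak/boundary co-localization uses a distance tolerance
(2 kb by default), with Fisher's exact test against the shuffled
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .caller import BoundarySet
from .genome import GenomeLayout
from .tracks import PeakSet, SignalTrack

__all__ = [
    "Profile",
    "EnrichmentProfile",
    "PairSiteSet",
    "ColocalizationResult",
    "occupancy_profile",
    "shuffled_background",
    "enrichment_ratio",
    "boundary_enrichment",
    "pair_sites",
    "colocalize",
    "venn_partition",
    "border_enrichment_test",
]


@dataclass
class Profile:
    offsets: np.ndarray  # window centers relative to the boundary center (bp)
    values: np.ndarray  # mean occupancy per window across centers
    n_centers: int
    n_clipped: int = 0


@dataclass
class EnrichmentProfile:
    offsets: np.ndarray
    observed: np.ndarray
    background: np.ndarray
    ratio: np.ndarray  # NaN where background == 0
    flagged: np.ndarray  # True where background == 0
    n_shuffles: int
    seed: int | None

    def central_ratio(self) -> float:
        mid = len(self.offsets) // 2
        c = self.ratio[mid - 1 : mid + 1]
        return float(np.nanmean(c))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "observed": self.observed,
                "background": self.background,
                "ratio": self.ratio,
            }
        )


def _window_offsets(flank: int, window: int) -> np.ndarray:
    n_windows = (2 * flank) // window
    return -flank + window / 2 + window * np.arange(n_windows)


def _profile(track: SignalTrack, centers_by_chrom: dict[str, np.ndarray], flank: int, window: int) -> Profile:
    offsets = _window_offsets(flank, window)
    n_windows = offsets.size
    sums = np.zeros(n_windows)
    n_total, n_clipped = 0, 0
    for chrom, centers in centers_by_chrom.items():
        centers = np.asarray(centers, dtype=np.float64)
        if centers.size == 0:
            continue
        length = track.genome.length(chrom)
        n_total += centers.size
        n_clipped += int(np.sum((centers - flank < 0) | (centers + flank > length)))
        for k in range(n_windows):
            a = centers + offsets[k] - window / 2
            # signal outside the chromosome counts as zero, window width fixed
            vals = track.integral(chrom, np.clip(a, 0, length), np.clip(a + window, 0, length))
            sums[k] += vals.sum() / window
    if n_total == 0:
        raise ValueError("no boundary centers supplied")
    return Profile(offsets, sums / n_total, n_total, n_clipped)


def occupancy_profile(
    track: SignalTrack, centers: BoundarySet, flank: int = 4000, window: int = 80
) -> Profile:
    """Mean occupancy per window across all boundary centers.

    With the defaults (±4 kb flank, 80 bp windows) the profile has 100
    windows. Centers whose flank extends past a chromosome end are
    clipped (out-of-range signal treated as zero) and counted in
    ``n_clipped``.
    """
    return _profile(track, centers.per_chrom(), flank, window)


def shuffled_background(
    track: SignalTrack,
    n_centers: dict[str, int] | int,
    genome: GenomeLayout,
    n_shuffles: int = 100,
    seed: int | None = None,
    flank: int = 4000,
    window: int = 80,
) -> Profile:
    """Profile from uniformly re-drawn centers, averaged over ``n_shuffles``.

    Per-chromosome center counts are preserved when a dict is given; an
    integer places all centers on the first chromosome.
    """
    if isinstance(n_centers, int):
        n_centers = {genome.names[0]: n_centers}
    if sum(n_centers.values()) == 0:
        raise ValueError("n_centers must be positive")
    rng = np.random.default_rng(seed)
    acc = None
    total = 0
    for _ in range(n_shuffles):
        draws = {
            chrom: rng.integers(0, genome.length(chrom), size=k)
            for chrom, k in n_centers.items()
            if k > 0
        }
        p = _profile(track, draws, flank, window)
        acc = p.values if acc is None else acc + p.values
        total += 1
    return Profile(_window_offsets(flank, window), acc / total, sum(n_centers.values()))


def enrichment_ratio(
    observed: Profile, background: Profile, n_shuffles: int = 0, seed: int | None = None
) -> EnrichmentProfile:
    """Elementwise observed/background ratio; zero-background windows are
    flagged and get NaN rather than infinity."""
    if observed.offsets.shape != background.offsets.shape or not np.allclose(
        observed.offsets, background.offsets
    ):
        raise ValueError("profiles are on different window grids")
    flagged = background.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(flagged, np.nan, observed.values / background.values)
    return EnrichmentProfile(
        observed.offsets, observed.values, background.values, ratio, flagged, n_shuffles, seed
    )


def boundary_enrichment(
    track: SignalTrack,
    centers: BoundarySet,
    genome: GenomeLayout,
    flank: int = 4000,
    window: int = 80,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> EnrichmentProfile:
    """Observed/shuffled occupancy ratio around boundary centers."""
    obs = occupancy_profile(track, centers, flank, window)
    per = {c: len(p) for c, p in centers.per_chrom().items()}
    bg = shuffled_background(track, per, genome, n_shuffles, seed, flank, window)
    return enrichment_ratio(obs, bg, n_shuffles, seed)


@dataclass
class PairSiteSet:
    """Loci where an anchor-protein peak co-occurs with a partner-protein peak."""

    pair: tuple[str, str]
    sites: pd.DataFrame  # columns: chrom, pos, anchor_index

    def __len__(self):
        return len(self.sites)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.sites[self.sites["chrom"] == chrom]
        return np.sort(sub["pos"].to_numpy(np.int64))


def pair_sites(anchor: PeakSet, partner: PeakSet, max_gap: int = 200) -> PairSiteSet:
    """Anchor peaks whose interval lies within ``max_gap`` bp of some partner
    peak interval (overlap counts as distance 0); the site position is the
    anchor peak summit."""
    rows = []
    for chrom in anchor.df["chrom"].unique():
        a = anchor.df[anchor.df["chrom"] == chrom]
        p = partner.df[partner.df["chrom"] == chrom].sort_values("start")
        if len(p) == 0:
            continue
        ps = p["start"].to_numpy(np.int64)
        pe = p["end"].to_numpy(np.int64)
        prefix_max_end = np.maximum.accumulate(pe)
        # partner qualifies iff start <= a.end + gap and end >= a.start - gap
        hi = np.searchsorted(ps, a["end"].to_numpy(np.int64) + max_gap, side="right")
        ok = (hi > 0) & (prefix_max_end[np.maximum(hi - 1, 0)] >= a["start"].to_numpy(np.int64) - max_gap)
        for idx, summit in zip(a.index[ok], a["summit"][ok]):
            rows.append({"chrom": chrom, "pos": int(summit), "anchor_index": int(idx)})
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "anchor_index"])
    return PairSiteSet((anchor.protein, partner.protein), sites)


@dataclass
class ColocalizationResult:
    n_borders: int
    n_sites: int
    borders_hit: int
    borders_hit_prop: float
    sites_at_borders: int
    sites_at_borders_prop: float
    tol: int
    venn_partition: dict | None = None
    fisher_p: float | None = None


def _site_positions(sites, chrom: str) -> np.ndarray:
    if isinstance(sites, PeakSet):
        return sites.summits(chrom)
    return sites.positions(chrom)


def _nearest_dist(query: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    if ref_sorted.size == 0:
        return np.full(query.shape, np.inf)
    idx = np.searchsorted(ref_sorted, query)
    left = np.abs(query - ref_sorted[np.clip(idx - 1, 0, ref_sorted.size - 1)])
    right = np.abs(ref_sorted[np.clip(idx, 0, ref_sorted.size - 1)] - query)
    return np.minimum(left, right)


def colocalize(sites, centers: BoundarySet, tol: int = 2000) -> ColocalizationResult:
    """Count borders with a site within ``tol`` bp and sites within ``tol`` of
    a border (each border/site counted once)."""
    per_centers = centers.per_chrom()
    chroms = set(per_centers)
    if isinstance(sites, PeakSet):
        chroms |= set(sites.df["chrom"].unique())
    else:
        chroms |= set(sites.sites["chrom"].unique())
    borders_hit = sites_hit = n_borders = n_sites = 0
    for chrom in chroms:
        c = np.asarray(per_centers.get(chrom, []), dtype=np.int64)
        s = _site_positions(sites, chrom)
        n_borders += c.size
        n_sites += s.size
        if c.size:
            borders_hit += int(np.sum(_nearest_dist(c.astype(float), s.astype(float)) <= tol))
        if s.size:
            sites_hit += int(np.sum(_nearest_dist(s.astype(float), c.astype(float)) <= tol))
    return ColocalizationResult(
        n_borders=n_borders,
        n_sites=n_sites,
        borders_hit=borders_hit,
        borders_hit_prop=borders_hit / n_borders if n_borders else float("nan"),
        sites_at_borders=sites_hit,
        sites_at_borders_prop=sites_hit / n_sites if n_sites else float("nan"),
        tol=tol,
    )


def venn_partition(site_sets: dict[str, object], centers: BoundarySet, tol: int = 2000) -> dict[str, int]:
    """Partition the borders hit by at least one protein into
    protein-combination regions (keys like 'BEAF-32+CP190')."""
    names = list(site_sets)
    hits = {}
    for name, sites in site_sets.items():
        h = []
        for chrom, c in centers.per_chrom().items():
            s = _site_positions(sites, chrom)
            h.append(_nearest_dist(c.astype(float), s.astype(float)) <= tol)
        hits[name] = np.concatenate(h) if h else np.array([], dtype=bool)
    out: dict[str, int] = {}
    n = len(next(iter(hits.values())))
    for i in range(n):
        combo = tuple(name for name in names if hits[name][i])
        if combo:
            key = "+".join(combo)
            out[key] = out.get(key, 0) + 1
    return out


def border_enrichment_test(
    borders_hit: int, n_borders: int, expected_hit_rate: float
) -> tuple[float, np.ndarray]:
    """Two-sided Fisher's exact test of observed border hits against the
    shuffled expectation (hit/miss x observed/shuffled 2x2 table)."""
    if borders_hit < 0 or n_borders < 0 or borders_hit > n_borders:
        raise ValueError("invalid counts")
    expected_hit = int(round(expected_hit_rate * n_borders))
    table = np.array(
        [[borders_hit, n_borders - borders_hit], [expected_hit, n_borders - expected_hit]]
    )
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return float(p), table
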