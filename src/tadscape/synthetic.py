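"""Seeded synthetic Hi-C generators with planted ground truth.

The generator emulates the statistical structure of a sub-kilobase
restriction-fragment Hi-C experiment on a compact genome:

* fragment lengths drawn geometrically around a 194 bp median (the
   4-cutter digest regime);
* a power-law contact decay (exponent ``alpha``) with multiplicative
  boosts for fragment pairs inside the same TAD, between adjacent TADs
  of particular chromatin-type pairs, and inside the same super-TAD,
  sampled as independent Poisson counts up to a maximum genomic
  separation;
* insulator peak tracks where protein pairs (a DNA-binding anchor plus
  a bridging partner) occupy a tunable fraction of planted boundaries
  on top of uniform background peaks, with modENCODE-style continuous
  occupancy tracks (positive baseline plus noise plus peak bumps);
* per-TAD epigenetic mark signals by chromatin type.

Every generator is a pure function of its design (which carries the
seed); per-purpose seeds are derived from the design seed so that the
fragment map, matrix, peaks and marks are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .caller import BoundarySet, Domain, DomainSet
from .chromstate import DEFAULT_MARK_GROUPS, DEFAULT_MARKS
from .genome import FragmentMap, GenomeLayout
from .matrix import ContactMatrix
from .tracks import PeakSet, SignalTrack

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "make_fragment_map",
    "plan_domains",
    "simulate_contact_matrix",
    "expected_intensity_matrix",
    "simulate_peak_track",
    "simulate_mark_signals",
    "make_border_prediction_data",
]

PROTEINS = ("BEAF-32", "CP190", "Chromator")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study conditions for the synthetic genome.

    Defaults mimic the published fly-genome geometry at reduced scale:
    a 10 Mb chromosome of ~194 bp fragments, alternating super-TADs of
    2-4 TADs (median ~16 kb) and inter-super-TAD strings of 1-4 slightly
    smaller TADs (median ~9 kb), unit power-law decay with a 4x
    within-TAD contact boost, and a 0.77 planted probability that a TAD
    border carries an insulator protein pair.
    """

    genome: GenomeLayout = GenomeLayout((("chrS", 10_000_000),))
    seed: int = 0
    median_fragment: int = 194
    # contact model: lambda(s) ~ (decay_offset + s)^(-alpha); the offset
    # flattens sub-TAD-scale decay (dense-block regime of sub-kb maps)
    alpha: float = 1.0
    decay_offset: int = 15_000
    within_boost: float = 4.0
    supertad_boost: float = 1.3
    neighbor_boosts: tuple[tuple[str, float], ...] = (("I-I", 1.4), ("P-P", 1.4), ("A-A", 0.7))
    depth: float = 2.7e7  # the published experiment's ~2.7M valid pairs per Mb
    max_distance: int = 150_000
    fragment_bias_range: tuple[float, float] | None = None
    deserts: tuple[tuple[str, int, int], ...] = ()  # bp intervals forced to zero coverage
    # domain plan (the genome is fully partitioned, as in the published map;
    # n_supertads caps the super-TAD count, None = fill the genome)
    n_supertads: int | None = None
    tads_per_supertad: tuple[int, int] = (2, 4)
    tads_per_inter: tuple[int, int] = (1, 4)
    supertad_tad_size: tuple[int, int] = (8_000, 28_000)
    inter_tad_size: tuple[int, int] = (5_000, 14_000)
    type_probs_super: tuple[tuple[str, float], ...] = (
        ("inactive", 0.65), ("polycomb", 0.15), ("active", 0.08), ("undetermined", 0.12),
    )
    type_probs_inter: tuple[tuple[str, float], ...] = (
        ("active", 0.65), ("undetermined", 0.15), ("inactive", 0.12), ("polycomb", 0.08),
    )
    explicit_plan: tuple | None = None  # ((chrom, start, end, type, super_id|None), ...)
    # insulator peaks / tracks
    border_pair_prob: float = 0.77
    solo_border_probs: tuple[tuple[str, float], ...] = (
        ("BEAF-32", 0.10), ("CP190", 0.08), ("Chromator", 0.05),
    )
    background_peak_density: float = 40.0  # peaks per Mb per protein
    peak_width: int = 300
    peak_jitter_sd: float = 100.0
    peak_amplitude: float = 5.0
    track_baseline: float = 1.0
    track_noise_sd: float = 0.2
    track_bin: int = 80
    # epigenetic marks
    mark_effect: float = 3.0
    mark_bin: int = 200

    def neighbor_boost(self, ta: str, tb: str) -> float:
        """Boost for adjacent TADs of types ta/tb (full names or A/I/P/U letters)."""
        short = {"active": "A", "inactive": "I", "polycomb": "P", "undetermined": "U"}
        key = "-".join(sorted(short.get(t, t) for t in (ta, tb)))
        return dict(self.neighbor_boosts).get(key, 1.0)


@dataclass
class GroundTruth:
    fragments: FragmentMap
    tads: DomainSet
    supertads: DomainSet
    tad_types: list[str]  # major type per TAD ('active'|'inactive'|'polycomb'|'undetermined')
    tad_super: list[int]  # super-TAD index per TAD, -1 for inter regions
    boundary_centers: BoundarySet = None
    border_sites: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    pair_site_positions: dict[str, np.ndarray] = field(default_factory=dict)
    fragment_bias: np.ndarray | None = None

    def __post_init__(self):
        if self.boundary_centers is None:
            from .caller import boundary_centers

            self.boundary_centers = boundary_centers(self.tads)

    def boundary_bins(self, chrom: str) -> np.ndarray:
        """Fragment index of the first fragment of each downstream TAD at a junction."""
        ds = self.tads.per_chrom().get(chrom, [])
        return np.array([b.start_bin for _, b in zip(ds, ds[1:])], dtype=np.int64)


def _rng(design: SyntheticDesign, *tags: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, *tags])


TYPE_SHORT = {"active": "A", "inactive": "I", "polycomb": "P", "undetermined": "U"}


def make_fragment_map(design: SyntheticDesign) -> FragmentMap:
    """Geometric fragment lengths with the target median, tiling each
    chromosome exactly (the last fragment is truncated)."""
    rng = _rng(design, 1)
    m = design.median_fragment
    p = 1.0 - 2.0 ** (-1.0 / m)
    cuts = {}
    for chrom, length in design.genome.chromosomes:
        if m >= length:
            cuts[chrom] = np.array([], dtype=np.int64)
            continue
        n_draw = int(length / m * 1.3) + 16
        pos = np.cumsum(rng.geometric(p, size=n_draw))
        while pos[-1] < length:
            pos = np.concatenate([pos, pos[-1] + np.cumsum(rng.geometric(p, size=n_draw))])
        cuts[chrom] = pos[pos < length]
    return FragmentMap.from_cuts(design.genome, cuts)


def _snap(fragments: FragmentMap, chrom: str, pos: int) -> int:
    """Snap a bp position to the nearest fragment boundary."""
    s = fragments.starts[chrom]
    length = fragments.genome.length(chrom)
    edges = np.concatenate([s, [length]])
    i = np.searchsorted(edges, pos)
    if i == 0:
        return 0
    if i >= edges.size:
        return int(edges[-1])
    return int(edges[i] if edges[i] - pos < pos - edges[i - 1] else edges[i - 1])


def plan_domains(design: SyntheticDesign, fragments: FragmentMap):
    """Plant the nested domain structure (TADs, their types, super-TADs),
    snapped to fragment boundaries.

    Returns (tads DomainSet, supertads DomainSet, types, super index per TAD).
    """
    rng = _rng(design, 2)
    raw: list[tuple[str, int, int, str, int]] = []
    supers: list[tuple[str, int, int]] = []
    if design.explicit_plan is not None:
        for chrom, start, end, typ, sid in design.explicit_plan:
            raw.append((chrom, int(start), int(end), typ, -1 if sid is None else int(sid)))
        n_sup = max((r[4] for r in raw), default=-1) + 1
        for sid in range(n_sup):
            members = [r for r in raw if r[4] == sid]
            supers.append((members[0][0], min(r[1] for r in members), max(r[2] for r in members)))
    else:
        names_s, probs_s = zip(*design.type_probs_super)
        names_i, probs_i = zip(*design.type_probs_inter)
        for chrom, length in design.genome.chromosomes:
            pos = 0
            n_built = 0
            cap = np.inf if design.n_supertads is None else design.n_supertads
            in_super = bool(rng.integers(2))
            while pos < length and n_built < cap:
                if in_super:
                    k = int(rng.integers(design.tads_per_supertad[0], design.tads_per_supertad[1] + 1))
                    lo, hi = design.supertad_tad_size
                    sid = len(supers)
                    start = pos
                    for _ in range(k):
                        size = int(rng.integers(lo, hi + 1))
                        end = min(pos + size, length)
                        if end - pos >= lo // 2:
                            raw.append((chrom, pos, end, str(rng.choice(names_s, p=probs_s)), sid))
                        pos = end
                        if pos >= length:
                            break
                    if pos > start:
                        supers.append((chrom, start, pos))
                    n_built += 1
                else:
                    k = int(rng.integers(design.tads_per_inter[0], design.tads_per_inter[1] + 1))
                    lo, hi = design.inter_tad_size
                    for _ in range(k):
                        size = int(rng.integers(lo, hi + 1))
                        end = min(pos + size, length)
                        if end - pos >= lo // 2:
                            raw.append((chrom, pos, end, str(rng.choice(names_i, p=probs_i)), -1))
                        pos = end
                        if pos >= length:
                            break
                in_super = not in_super
    # snap to fragment boundaries and build Domain objects
    tads, types, tad_super = [], [], []
    for chrom, start, end, typ, sid in raw:
        s = _snap(fragments, chrom, start)
        e = _snap(fragments, chrom, end)
        if e - s < 2 * design.median_fragment:
            continue
        sb = int(fragments.locate(chrom, s))
        eb = int(fragments.locate(chrom, e - 1))
        tads.append(Domain(chrom, sb, eb, s, e, 0.0, float("nan")))
        types.append(typ)
        tad_super.append(sid)
    sup_domains = []
    for chrom, start, end in supers:
        s = _snap(fragments, chrom, start)
        e = _snap(fragments, chrom, end)
        if e <= s:
            continue
        sb = int(fragments.locate(chrom, s))
        eb = int(fragments.locate(chrom, e - 1))
        sup_domains.append(Domain(chrom, sb, eb, s, e, 0.0, float("nan")))
    return (
        DomainSet("TAD", tads, axis=fragments),
        DomainSet("super-TAD", sup_domains, axis=fragments),
        types,
        tad_super,
    )


def _per_fragment_annotations(design, fragments, tads, types, tad_super, chrom):
    """tad index (-1 outside), type code and super index per fragment."""
    n = fragments.n_chrom(chrom)
    tad_of = np.full(n, -1, dtype=np.int64)
    super_of = np.full(n, -1, dtype=np.int64)
    type_of = np.zeros(n, dtype="U1")
    ds = [(i, d) for i, d in enumerate(tads) if d.chrom == chrom]
    for i, d in ds:
        tad_of[d.start_bin : d.end_bin + 1] = i
        super_of[d.start_bin : d.end_bin + 1] = tad_super[i]
        type_of[d.start_bin : d.end_bin + 1] = TYPE_SHORT[types[i]]
    return tad_of, super_of, type_of


def _neighbor_boost_table(design, tads: DomainSet, types: list[str]) -> np.ndarray:
    """nb[t] = boost for contacts between TAD t and TAD t+1 (same chromosome)."""
    ds = list(tads)
    nb = np.ones(max(len(ds), 1))
    for t in range(len(ds) - 1):
        if ds[t].chrom == ds[t + 1].chrom:
            nb[t] = design.neighbor_boost(types[t], types[t + 1])
    return nb


def _intensity_diag(design, mids, tad_of, super_of, nb_table, d, bias=None):
    """Unscaled intensity for the d-th diagonal (pairs (i, i+d))."""
    n = mids.size
    sep = (mids[d:] - mids[: n - d]).astype(np.float64)
    lam = np.where(
        sep <= design.max_distance,
        (design.decay_offset + sep) ** (-design.alpha),
        0.0,
    )
    a, b = tad_of[: n - d], tad_of[d:]
    same_tad = (a >= 0) & (a == b)
    lam *= np.where(same_tad, design.within_boost, 1.0)
    adjacent = (a >= 0) & (b == a + 1)
    if adjacent.any():
        boost = np.ones(n - d)
        boost[adjacent] = nb_table[a[adjacent]]
        lam *= boost
    sa, sb_ = super_of[: n - d], super_of[d:]
    lam *= np.where((sa >= 0) & (sa == sb_) & ~same_tad, design.supertad_boost, 1.0)
    if bias is not None:
        lam *= bias[: n - d] * bias[d:]
    return lam


def _desert_mask(design, fragments, chrom):
    n = fragments.n_chrom(chrom)
    dead = np.zeros(n, dtype=bool)
    for c, a, b in design.deserts:
        if c == chrom:
            sb = int(fragments.locate(chrom, max(a, 0)))
            eb = int(fragments.locate(chrom, min(b, fragments.genome.length(chrom)) - 1))
            dead[sb : eb + 1] = True
    return dead


def simulate_contact_matrix(
    design: SyntheticDesign, fragments: FragmentMap, truth: GroundTruth, replicate: int = 0
) -> ContactMatrix:
    """Poisson-sampled contact counts from the planted intensity model.

    lambda(i, j) is proportional to sep^(-alpha) times the within-TAD,
    adjacent-type and super-TAD boosts (and planted fragment biases when
    configured), scaled so the expected total equals ``depth``.
    ``replicate`` selects an independent Poisson sample of the same
    intensity map.
    """
    rng = _rng(design, 3, replicate)
    tads, types, tad_super = truth.tads, truth.tad_types, truth.tad_super
    bias = truth.fragment_bias
    nb_table = _neighbor_boost_table(design, tads, types)
    # pass 1: total unscaled intensity
    total = 0.0
    per_chrom = {}
    for chrom in design.genome.names:
        mids = fragments.midpoints(chrom)
        n = mids.size
        tad_of, super_of, type_of = _per_fragment_annotations(
            design, fragments, tads, types, tad_super, chrom
        )
        dead = _desert_mask(design, fragments, chrom)
        reach = np.searchsorted(mids, mids + design.max_distance, side="right") - np.arange(n) - 1
        span = min(n - 1, int(reach.max())) if n > 1 else 0
        b = None if bias is None else bias[fragments.chrom_slice(chrom)]
        per_chrom[chrom] = (mids, tad_of, super_of, dead, span, b)
        for d in range(1, span + 1):
            lam = _intensity_diag(design, mids, tad_of, super_of, nb_table, d, b)
            if dead.any():
                lam[dead[: n - d] | dead[d:]] = 0.0
            total += float(lam.sum())
    if total == 0 or design.depth <= 0:
        return ContactMatrix(fragments, sp.csr_matrix((fragments.n, fragments.n)))
    scale = design.depth / total
    rows, cols, vals = [], [], []
    for chrom in design.genome.names:
        mids, tad_of, super_of, dead, span, b = per_chrom[chrom]
        n = mids.size
        o = fragments.offsets[chrom]
        for d in range(1, span + 1):
            lam = _intensity_diag(design, mids, tad_of, super_of, nb_table, d, b)
            if dead.any():
                lam[dead[: n - d] | dead[d:]] = 0.0
            counts = rng.poisson(lam * scale)
            nz = np.flatnonzero(counts)
            if nz.size:
                rows.append(nz + o)
                cols.append(nz + d + o)
                vals.append(counts[nz])
    if not rows:
        return ContactMatrix(fragments, sp.csr_matrix((fragments.n, fragments.n)))
    counts = sp.coo_matrix(
        (
            np.concatenate(vals).astype(np.float64),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(fragments.n, fragments.n),
    ).tocsr()
    return ContactMatrix(fragments, counts)


def expected_intensity_matrix(
    design: SyntheticDesign, fragments: FragmentMap, truth: GroundTruth
) -> ContactMatrix:
    """The deterministic (noise-free) intensity map itself, as a matrix."""
    tads, types, tad_super = truth.tads, truth.tad_types, truth.tad_super
    nb_table = _neighbor_boost_table(design, tads, types)
    total = 0.0
    diags = {}
    for chrom in design.genome.names:
        mids = fragments.midpoints(chrom)
        n = mids.size
        tad_of, super_of, type_of = _per_fragment_annotations(
            design, fragments, tads, types, tad_super, chrom
        )
        dead = _desert_mask(design, fragments, chrom)
        reach = np.searchsorted(mids, mids + design.max_distance, side="right") - np.arange(n) - 1
        span = min(n - 1, int(reach.max())) if n > 1 else 0
        b = None if truth.fragment_bias is None else truth.fragment_bias[fragments.chrom_slice(chrom)]
        lams = []
        for d in range(1, span + 1):
            lam = _intensity_diag(design, mids, tad_of, super_of, nb_table, d, b)
            if dead.any():
                lam[dead[: n - d] | dead[d:]] = 0.0
            lams.append(lam)
            total += float(lam.sum())
        diags[chrom] = lams
    scale = design.depth / total if total > 0 else 0.0
    rows, cols, vals = [], [], []
    for chrom, lams in diags.items():
        o = fragments.offsets[chrom]
        n = fragments.n_chrom(chrom)
        for d, lam in enumerate(lams, start=1):
            nz = np.flatnonzero(lam)
            rows.append(nz + o)
            cols.append(nz + d + o)
            vals.append(lam[nz] * scale)
    counts = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(fragments.n, fragments.n),
    ).tocsr()
    return ContactMatrix(fragments, counts)


def build_ground_truth(design: SyntheticDesign, fragments: FragmentMap) -> GroundTruth:
    tads, supertads, types, tad_super = plan_domains(design, fragments)
    bias = None
    if design.fragment_bias_range is not None:
        rng = _rng(design, 6)
        lo, hi = design.fragment_bias_range
        bias = np.exp(rng.uniform(np.log(lo), np.log(hi), size=fragments.n))
    return GroundTruth(fragments, tads, supertads, types, tad_super, fragment_bias=bias)


def simulate_peak_track(
    design: SyntheticDesign, truth: GroundTruth
) -> tuple[dict[str, PeakSet], dict[str, SignalTrack]]:
    """Insulator peak calls and continuous occupancy tracks.

    At each planted boundary, with probability ``border_pair_prob`` a
    BEAF-32 peak plus a partner (CP190 or Chromator, equal odds) are
    placed at the center with Gaussian jitter; each protein additionally
    occupies boundaries alone with its solo probability, and uniform
    background peaks are added at ``background_peak_density``. Tracks
    are a positive baseline plus binned Gaussian noise plus box-shaped
    peak bumps (modENCODE-style normalized occupancy).
    """
    rng = _rng(design, 4)
    genome = design.genome
    peaks: dict[str, list[tuple[str, int]]] = {p: [] for p in PROTEINS}
    truth.border_sites = {p: {} for p in PROTEINS}
    pair_pos: dict[str, list[int]] = {}
    solo = dict(design.solo_border_probs)
    for chrom, centers in truth.boundary_centers.per_chrom().items():
        length = genome.length(chrom)
        border_sites = {p: [] for p in PROTEINS}
        for c in centers:
            here = set()
            if rng.random() < design.border_pair_prob:
                partner = "CP190" if rng.random() < 0.5 else "Chromator"
                here.update(("BEAF-32", partner))
            for p in PROTEINS:
                if p not in here and rng.random() < solo.get(p, 0.0):
                    here.add(p)
            for p in here:
                pos = int(np.clip(round(c + rng.normal(0, design.peak_jitter_sd)), 0, length - 1))
                peaks[p].append((chrom, pos))
                border_sites[p].append(pos)
            if {"BEAF-32", "CP190"} <= here or {"BEAF-32", "Chromator"} <= here:
                pair_pos.setdefault(chrom, []).append(int(c))
        for p in PROTEINS:
            truth.border_sites[p][chrom] = np.asarray(sorted(border_sites[p]), dtype=np.int64)
    for p in PROTEINS:
        for chrom, length in genome.chromosomes:
            n_bg = rng.poisson(design.background_peak_density * length / 1e6)
            for pos in rng.integers(0, length, size=n_bg):
                peaks[p].append((chrom, int(pos)))
    truth.pair_site_positions = {c: np.asarray(sorted(v), dtype=np.int64) for c, v in pair_pos.items()}
    half = design.peak_width // 2
    peaksets, tracksets = {}, {}
    for p in PROTEINS:
        rows = []
        for chrom, pos in peaks[p]:
            length = genome.length(chrom)
            start = max(0, pos - half)
            end = min(length, pos + half)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "summit": int(np.clip(pos, start, end)),
                    "signal": float(design.peak_amplitude * rng.uniform(0.8, 1.2)),
                }
            )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "signal"])
        peaksets[p] = PeakSet(p, df.sort_values(["chrom", "start"]).reset_index(drop=True))
        values = {}
        for chrom, length in genome.chromosomes:
            nbins = -(-length // design.track_bin)
            v = design.track_baseline + rng.normal(0, design.track_noise_sd, size=nbins)
            np.maximum(v, 0.0, out=v)
            sub = peaksets[p].df[peaksets[p].df["chrom"] == chrom]
            for s, e, amp in zip(sub["start"], sub["end"], sub["signal"]):
                b0, b1 = int(s // design.track_bin), int(-(-e // design.track_bin))
                v[b0:b1] += amp
            values[chrom] = v
        tracksets[p] = SignalTrack.from_dense(genome, design.track_bin, values)
    return peaksets, tracksets


def simulate_mark_signals(
    design: SyntheticDesign,
    truth: GroundTruth,
    marks: list[str] | None = None,
    mark_groups: dict[str, list[str]] | None = None,
) -> dict[str, SignalTrack]:
    """Per-mark tracks: unit Gaussian bin noise plus ``mark_effect`` inside
    TADs whose chromatin type matches the mark's group."""
    marks = marks or DEFAULT_MARKS
    mark_groups = mark_groups or DEFAULT_MARK_GROUPS
    group_of = {m: g for g, ms in mark_groups.items() for m in ms}
    rng = _rng(design, 5)
    out = {}
    binsize = design.mark_bin
    for mark in marks:
        values = {}
        for chrom, length in design.genome.chromosomes:
            nbins = -(-length // binsize)
            v = rng.normal(0.0, 1.0, size=nbins)
            values[chrom] = v
        group = group_of.get(mark)
        if group is not None:
            for d, typ in zip(truth.tads, truth.tad_types):
                if typ == group:
                    b0 = int(d.start_bp // binsize)
                    b1 = int(-(-d.end_bp // binsize))
                    values[d.chrom][b0:b1] += design.mark_effect
        out[mark] = SignalTrack.from_dense(design.genome, binsize, values)
    return out


def make_border_prediction_data(
    n_fragments: int = 2000,
    border_rate: float = 0.05,
    pair_hit_rate: float = 0.77,
    pair_background_rate: float = 0.02,
    n_marks: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table and labels for border-prediction benchmarks.

    Pair-site indicator features carry the border signal (present at
    ``pair_hit_rate`` of borders, ``pair_background_rate`` elsewhere);
    "active-mark" features are noise correlated with alternating domains
    but carry no border information.
    """
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_fragments) < border_rate).astype(int)
    pair = np.where(
        labels == 1,
        rng.random(n_fragments) < pair_hit_rate,
        rng.random(n_fragments) < pair_background_rate,
    ).astype(float)
    pair += rng.normal(0, 0.05, size=n_fragments)  # track-derived, not perfectly binary
    # domain-structured marks: blocks of ~30 fragments share a level
    block = np.repeat(np.arange(n_fragments // 30 + 1), 30)[:n_fragments]
    level = rng.normal(0, 1, size=block.max() + 1)
    marks = {
        f"mark{j}": level[block] * 0.8 + rng.normal(0, 1.0, size=n_fragments)
        for j in range(n_marks)
    }
    feats = pd.DataFrame({"pair_site": pair, **marks})
    return feats, labels
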