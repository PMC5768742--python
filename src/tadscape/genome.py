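"""Genome coordinate layer: chromosome layout, restriction-fragment maps, in-silico digestion.

All coordinates are 0-based, half-open, matching BED conventions. A
:class:`FragmentMap` is an ordered partition of every chromosome into
restriction fragments; it is the coordinate system for all
fragment-resolution work downstream (contact matrices, domain calls,
feature tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "FragmentMap",
    "BinnedAxis",
    "digest_genome",
    "read_fragment_map",
    "write_fragment_map",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered list of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        chroms = tuple((str(c), int(n)) for c, n in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(n <= 0 for _, n in chroms):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]


@dataclass
class FragmentMap:
    """Ordered partition of each chromosome into restriction fragments.

    ``starts[chrom]`` / ``ends[chrom]`` are sorted arrays of 0-based
    half-open intervals that tile the chromosome without gaps or
    overlaps. Fragment indices are zero-based and genome-wide, strictly
    increasing in genome order.
    """

    genome: GenomeLayout
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    offsets: dict[str, int] = field(init=False)

    def __post_init__(self):
        off = 0
        offsets = {}
        for chrom, length in self.genome.chromosomes:
            s = np.asarray(self.starts[chrom], dtype=np.int64)
            e = np.asarray(self.ends[chrom], dtype=np.int64)
            if s.size == 0:
                raise ValueError(f"{chrom}: empty fragment list")
            if s[0] != 0 or e[-1] != length:
                raise ValueError(f"{chrom}: fragments do not span the chromosome")
            if np.any(e <= s):
                bad = int(np.flatnonzero(e <= s)[0])
                raise ValueError(f"{chrom}: fragment {bad} is empty or inverted")
            gaps = s[1:] - e[:-1]
            if np.any(gaps != 0):
                bad = int(np.flatnonzero(gaps != 0)[0])
                kind = "overlap" if gaps[bad] < 0 else "gap"
                raise ValueError(
                    f"{chrom}: {kind} between fragments {bad} and {bad + 1} "
                    f"(end={e[bad]}, next start={s[bad + 1]})"
                )
            self.starts[chrom] = s
            self.ends[chrom] = e
            offsets[chrom] = off
            off += s.size
        self.offsets = offsets
        self._n = off

    # -- axis protocol (shared with BinnedAxis) ------------------------------
    @property
    def n(self) -> int:
        return self._n

    def n_chrom(self, chrom: str) -> int:
        return self.starts[chrom].size

    def chrom_slice(self, chrom: str) -> slice:
        o = self.offsets[chrom]
        return slice(o, o + self.n_chrom(chrom))

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts[chrom] + self.ends[chrom]) // 2

    def bin_start(self, chrom: str, i: int) -> int:
        return int(self.starts[chrom][i])

    def bin_end(self, chrom: str, i: int) -> int:
        return int(self.ends[chrom][i])

    # -- lookups --------------------------------------------------------------
    def lengths(self) -> np.ndarray:
        return np.concatenate(
            [self.ends[c] - self.starts[c] for c in self.genome.names]
        )

    def locate(self, chrom: str, pos) -> np.ndarray:
        """Local fragment index containing each position (vectorised)."""
        pos = np.asarray(pos, dtype=np.int64)
        length = self.genome.length(chrom)
        if np.any(pos < 0) or np.any(pos >= length):
            bad = pos[(pos < 0) | (pos >= length)][0]
            raise ValueError(f"position {bad} outside {chrom} [0, {length})")
        return np.searchsorted(self.starts[chrom], pos, side="right") - 1

    def locate_global(self, chrom: str, pos) -> np.ndarray:
        return self.locate(chrom, pos) + self.offsets[chrom]

    def median_fragment_length(self) -> float:
        return float(np.median(self.lengths()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.names:
            o = self.offsets[chrom]
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": self.starts[chrom],
                        "end": self.ends[chrom],
                        "fragment_index": np.arange(o, o + self.n_chrom(chrom)),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_cuts(cls, genome: GenomeLayout, cuts: dict[str, np.ndarray]) -> "FragmentMap":
        """Build from per-chromosome internal cut positions (0 < cut < length)."""
        starts, ends = {}, {}
        for chrom, length in genome.chromosomes:
            c = np.unique(np.asarray(cuts.get(chrom, []), dtype=np.int64))
            c = c[(c > 0) & (c < length)]
            s = np.concatenate([[0], c])
            e = np.concatenate([c, [length]])
            starts[chrom], ends[chrom] = s, e
        return cls(genome, starts, ends)


@dataclass(frozen=True)
class BinnedAxis:
    """Fixed-width bin axis over a genome (last bin of a chromosome may be short)."""

    genome: GenomeLayout
    binsize: int

    @property
    def n(self) -> int:
        return sum(self.n_chrom(c) for c in self.genome.names)

    def n_chrom(self, chrom: str) -> int:
        return -(-self.genome.length(chrom) // self.binsize)

    @property
    def offsets(self) -> dict[str, int]:
        off, out = 0, {}
        for c in self.genome.names:
            out[c] = off
            off += self.n_chrom(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        o = self.offsets[chrom]
        return slice(o, o + self.n_chrom(chrom))

    def midpoints(self, chrom: str) -> np.ndarray:
        n = self.n_chrom(chrom)
        starts = np.arange(n, dtype=np.int64) * self.binsize
        ends = np.minimum(starts + self.binsize, self.genome.length(chrom))
        return (starts + ends) // 2

    def bin_start(self, chrom: str, i: int) -> int:
        return int(i) * self.binsize

    def bin_end(self, chrom: str, i: int) -> int:
        return min((int(i) + 1) * self.binsize, self.genome.length(chrom))


def digest_genome(sequences: dict[str, str], motif: str = "GATC") -> tuple[FragmentMap, float]:
    """In-silico restriction digest.

    Cut positions are placed at every motif occurrence start on the
    forward strand (DpnII cleaves 5' of GATC, so every fragment except
    the first of a chromosome begins with the motif). Returns the
    fragment map and the genome-wide median fragment length.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    layout, cuts = [], {}
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"{chrom}: empty sequence")
        seq = seq.upper()
        layout.append((chrom, len(seq)))
        pos, found = 0, []
        while True:
            hit = seq.find(motif, pos)
            if hit < 0:
                break
            found.append(hit)
            pos = hit + 1
        cuts[chrom] = np.asarray(found, dtype=np.int64)
    genome = GenomeLayout(tuple(layout))
    fm = FragmentMap.from_cuts(genome, cuts)
    return fm, fm.median_fragment_length()


def write_fragment_map(fm: FragmentMap, path) -> None:
    """4-column BED: chrom, start, end, fragment_index."""
    fm.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_fragment_map(path, genome: GenomeLayout | None = None) -> FragmentMap:
    """Read a 4-column BED fragment map; validates tiling (gaps/overlaps rejected).

    When ``genome`` is omitted, chromosome lengths are taken from the
    last fragment end per chromosome, in file order.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "fragment_index"],
        dtype={"chrom": str},
    )
    if genome is None:
        lengths = df.groupby("chrom", sort=False)["end"].max()
        genome = GenomeLayout(tuple(lengths.items()))
    starts, ends = {}, {}
    for chrom in genome.names:
        sub = df[df["chrom"] == chrom]
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"{chrom}: fragments not sorted by start")
        starts[chrom] = sub["start"].to_numpy(np.int64)
        ends[chrom] = sub["end"].to_numpy(np.int64)
    return FragmentMap(genome, starts, ends)
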