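"""Genomic interval containers: piecewise-constant signal tracks and peak sets.

A :class:`SignalTrack` is a step function over each chromosome backed by
breakpoint/value arrays with a prefix integral, so that exact means over
arbitrary intervals are O(log n). Regions absent from a bedGraph are
treated as zero signal (and count toward means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = ["SignalTrack", "PeakSet"]


@dataclass
class SignalTrack:
    """Piecewise-constant genome-wide signal.

    ``breaks[chrom]`` is a sorted array starting at 0 and ending at the
    chromosome length; ``values[chrom]`` has one value per interval
    between consecutive breakpoints.
    """

    genome: GenomeLayout
    breaks: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    _cum: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self):
        self._cum = {}
        for chrom, length in self.genome.chromosomes:
            b = np.asarray(self.breaks[chrom], dtype=np.float64)
            v = np.asarray(self.values[chrom], dtype=np.float64)
            if b[0] != 0 or b[-1] != length or v.size != b.size - 1:
                raise ValueError(f"{chrom}: breakpoints must span [0, {length}]")
            self.breaks[chrom] = b
            self.values[chrom] = v
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(v * np.diff(b))])

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_dense(cls, genome: GenomeLayout, binsize: int, values: dict[str, np.ndarray]):
        """Binned values (last bin may be truncated to the chromosome end)."""
        breaks, vals = {}, {}
        for chrom, length in genome.chromosomes:
            v = np.asarray(values[chrom], dtype=np.float64)
            b = np.minimum(np.arange(v.size + 1, dtype=np.float64) * binsize, length)
            breaks[chrom], vals[chrom] = b, v
        return cls(genome, breaks, vals)

    @classmethod
    def from_bedgraph(cls, path, genome: GenomeLayout):
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        breaks, vals = {}, {}
        for chrom, length in genome.chromosomes:
            sub = df[df["chrom"] == chrom].sort_values("start")
            b, v, pos = [0.0], [], 0
            for s, e, val in zip(sub["start"], sub["end"], sub["value"]):
                if s > pos:  # gap -> zero fill
                    b.append(float(s))
                    v.append(0.0)
                b.append(float(min(e, length)))
                v.append(float(val))
                pos = e
            if pos < length:
                b.append(float(length))
                v.append(0.0)
            breaks[chrom] = np.asarray(b)
            vals[chrom] = np.asarray(v)
        return cls(genome, breaks, vals)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.genome.names:
                b, v = self.breaks[chrom], self.values[chrom]
                for s, e, val in zip(b[:-1], b[1:], v):
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{val:.6g}\n")

    # -- queries --------------------------------------------------------------
    def _F(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Prefix integral of the step function at positions x (clipped)."""
        b, v, cum = self.breaks[chrom], self.values[chrom], self._cum[chrom]
        x = np.clip(np.asarray(x, dtype=np.float64), 0.0, b[-1])
        idx = np.clip(np.searchsorted(b, x, side="right") - 1, 0, v.size - 1)
        return cum[idx] + (x - b[idx]) * v[idx]

    def integral(self, chrom: str, start, end) -> np.ndarray:
        return self._F(chrom, end) - self._F(chrom, start)

    def mean(self, chrom: str, start, end) -> np.ndarray:
        start = np.asarray(start, dtype=np.float64)
        end = np.asarray(end, dtype=np.float64)
        width = end - start
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(width > 0, self.integral(chrom, start, end) / width, np.nan)

    def genome_mean(self) -> float:
        total = sum(self._cum[c][-1] for c in self.genome.names)
        return total / self.genome.total_length

    def genome_sd(self) -> float:
        m = self.genome_mean()
        sq = 0.0
        for c in self.genome.names:
            w = np.diff(self.breaks[c])
            sq += float(np.sum(self.values[c] ** 2 * w))
        var = sq / self.genome.total_length - m * m
        return float(np.sqrt(max(var, 0.0)))

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        if self.genome.chromosomes != other.genome.chromosomes:
            raise ValueError("tracks on different genomes")
        breaks, vals = {}, {}
        for chrom in self.genome.names:
            b = np.union1d(self.breaks[chrom], other.breaks[chrom])
            mid = (b[:-1] + b[1:]) / 2
            va = self._value_at(chrom, mid)
            vb = other._value_at(chrom, mid)
            breaks[chrom], vals[chrom] = b, va + vb
        return SignalTrack(self.genome, breaks, vals)

    def _value_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        b, v = self.breaks[chrom], self.values[chrom]
        idx = np.clip(np.searchsorted(b, x, side="right") - 1, 0, v.size - 1)
        return v[idx]


@dataclass
class PeakSet:
    """Peak calls for one protein: intervals with summits and signal values."""

    protein: str
    df: pd.DataFrame  # columns: chrom, start, end, summit, signal

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("peak with start >= end")
            bad = (df["summit"] < df["start"]) | (df["summit"] > df["end"])
            if bad.any():
                raise ValueError("summit outside peak interval")
        self.df = df

    def __len__(self):
        return len(self.df)

    def summits(self, chrom: str) -> np.ndarray:
        sub = self.df[self.df["chrom"] == chrom]
        return np.sort(sub["summit"].to_numpy(np.int64))

    @classmethod
    def from_narrowpeak(cls, path, protein: str) -> "PeakSet":
        """BED6+4 narrowPeak; summit = start + 10th-column offset when
        present and non-negative, else the interval midpoint."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        out = pd.DataFrame(
            {
                "chrom": df[0],
                "start": df[1].astype(np.int64),
                "end": df[2].astype(np.int64),
            }
        )
        out["signal"] = df[6].astype(float) if df.shape[1] > 6 else 1.0
        if df.shape[1] >= 10:
            offset = df[9].astype(np.int64)
            out["summit"] = np.where(
                offset >= 0, out["start"] + offset, (out["start"] + out["end"]) // 2
            )
        else:
            out["summit"] = (out["start"] + out["end"]) // 2
        return cls(protein, out[["chrom", "start", "end", "summit", "signal"]])

    def to_narrowpeak(self, path) -> None:
        df = self.df
        with open(path, "w") as fh:
            for i, r in df.iterrows():
                fh.write(
                    f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                    f"{self.protein}_{i}\t0\t.\t{r['signal']:.6g}\t-1\t-1\t"
                    f"{int(r['summit'] - r['start'])}\n"
                )
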