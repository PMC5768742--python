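"""Chromatin-state typing of TADs from epigenetic mark enrichment.

Each TAD is summarised by the mean of each genome-wide Z-scored mark
track over the TAD interval (one row per TAD, one column per mark).
Rows are clustered with k-means (k=8 by default) and clusters are
grouped into four major types - active, inactive, polycomb, or
undetermined - according to which mark group dominates the cluster
centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .caller import DomainSet, NestingResult
from .tracks import SignalTrack

__all__ = [
    "DEFAULT_MARK_GROUPS",
    "tad_mark_enrichment",
    "kmeans_types",
    "assign_major_types",
    "type_localization_test",
    "KMeansResult",
]

# Conventional mark panel: 15 histone modifications / chromosomal proteins.
# Users override with their own group mapping; unlisted marks are ignored
# when scoring cluster centroids (they still enter the clustering).
DEFAULT_MARK_GROUPS: dict[str, list[str]] = {
    "active": ["H3K4me3", "H3K36me3", "H4K16ac", "RNA-Pol-II", "Chriz"],
    "inactive": ["H3K9me2", "H3K9me3", "SU(VAR)3-9", "Lamin", "H1"],
    "polycomb": ["H3K27me3", "Pc", "E(z)"],
}
NEUTRAL_MARKS = ["H4", "H2Av"]
DEFAULT_MARKS = sum(DEFAULT_MARK_GROUPS.values(), []) + NEUTRAL_MARKS


def tad_mark_enrichment(tracks: dict[str, SignalTrack], domains: DomainSet) -> pd.DataFrame:
    """Per-TAD mean of each genome-wide Z-scored mark track.

    A constant track Z-scores to zero everywhere (flagged by a warning).
    Row order matches the domain set order.
    """
    rows = [(d.chrom, d.start_bp, d.end_bp) for d in domains]
    out = {}
    for mark, track in tracks.items():
        m, sd = track.genome_mean(), track.genome_sd()
        if sd == 0:
            warnings.warn(f"mark {mark!r}: constant track, Z-scores set to 0", stacklevel=2)
            out[mark] = np.zeros(len(rows))
            continue
        vals = np.empty(len(rows))
        for i, (chrom, s, e) in enumerate(rows):
            vals[i] = (float(track.mean(chrom, s, e)) - m) / sd
        out[mark] = vals
    return pd.DataFrame(out, index=pd.RangeIndex(len(rows), name="tad"))


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    inertia_trace: list[float]  # per-iteration objective of the winning restart


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans_types(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 8,
    seed: int | None = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> KMeansResult:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by
    within-cluster sum of squares; deterministic under ``seed``.

    The objective is checked to be non-increasing across iterations
    (a violation raises, since it indicates a defect, not noise).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers = _kmeanspp(X, k, rng)
        trace: list[float] = []
        labels = None
        for _it in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            inertia = float(d2[np.arange(n), new_labels].sum())
            if trace and inertia > trace[-1] * (1 + 1e-9) + 1e-12:
                raise RuntimeError("k-means objective increased between iterations")
            trace.append(inertia)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                sel = labels == j
                if sel.any():
                    centers[j] = X[sel].mean(axis=0)
                else:  # empty cluster: reseed at the farthest point
                    far = d2[np.arange(n), labels].argmax()
                    centers[j] = X[far]
        if best is None or trace[-1] < best.inertia:
            best = KMeansResult(labels.copy(), centers.copy(), trace[-1], trace)
    return best


def assign_major_types(
    kres: KMeansResult,
    mark_columns: list[str],
    mark_groups: dict[str, list[str]] | None = None,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Map clusters to major types by the dominant mark-group centroid mean.

    A cluster is typed by the group with the highest mean centroid Z
    among its marks if that mean exceeds ``tau`` (Z units); otherwise
    'undetermined'. Ties between groups are flagged undetermined.
    """
    mark_groups = mark_groups or DEFAULT_MARK_GROUPS
    col_idx = {m: i for i, m in enumerate(mark_columns)}
    cluster_types = {}
    for c in range(kres.centroids.shape[0]):
        means = {}
        for group, marks in mark_groups.items():
            cols = [col_idx[m] for m in marks if m in col_idx]
            if cols:
                means[group] = float(kres.centroids[c, cols].mean())
        if not means:
            cluster_types[c] = "undetermined"
            continue
        top = max(means.values())
        winners = [g for g, v in means.items() if v == top]
        if top <= tau or len(winners) > 1:
            cluster_types[c] = "undetermined"
        else:
            cluster_types[c] = winners[0]
    return pd.DataFrame(
        {
            "cluster": kres.labels,
            "major_type": [cluster_types[int(c)] for c in kres.labels],
        },
        index=pd.RangeIndex(len(kres.labels), name="tad"),
    )


@dataclass
class LocalizationTest:
    table: pd.DataFrame  # (active, inactive) x (super-TAD, inter-super-TAD)
    p: float
    prop_inactive_in_super: float
    prop_active_in_inter: float


def type_localization_test(
    classes: pd.DataFrame, nesting: NestingResult
) -> LocalizationTest | None:
    """Fisher's exact test of active-vs-inactive TAD type against
    super-TAD vs inter-super-TAD localization."""
    merged = classes.join(nesting.assignment.set_index("tad")["region"])
    merged = merged[
        merged["major_type"].isin(["active", "inactive"])
        & merged["region"].isin(["super-TAD", "inter-super-TAD"])
    ]
    table = pd.crosstab(merged["major_type"], merged["region"])
    if table.shape != (2, 2) or (table.sum(axis=1) == 0).any():
        warnings.warn("empty type or localization class; test skipped", stacklevel=2)
        return None
    table = table.reindex(
        index=["active", "inactive"], columns=["super-TAD", "inter-super-TAD"]
    ).fillna(0).astype(int)
    _, p = scipy.stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    n_inactive = table.loc["inactive"].sum()
    n_active = table.loc["active"].sum()
    return LocalizationTest(
        table=table,
        p=float(p),
        prop_inactive_in_super=float(table.loc["inactive", "super-TAD"] / n_inactive),
        prop_active_in_inter=float(table.loc["active", "inter-super-TAD"] / n_active),
    )
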