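"""Logistic-regression prediction of TAD-border fragments from marker signals.

Features are per-fragment marker values (mean of a signal track over the
fragment interval), Z-transformed per column. Labels mark fragments that
contain a boundary center. A model is fit on a random half of the data
and evaluated on the held-out half by ROC/AUC, where the AUC is the
Mann-Whitney rank statistic (ties contribute 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .caller import BoundarySet
from .genome import FragmentMap
from .tracks import SignalTrack

__all__ = [
    "ztransform",
    "fragment_signal",
    "label_fragments",
    "fit_border_model",
    "roc_auc",
    "ROCResult",
    "BorderModel",
]


def ztransform(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-column Z-transform ((x - mean) / sd, population sd).

    Zero-variance columns are dropped with a warning. Idempotent on
    already-standardised columns.
    """
    out = {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or x.size < 2:
            warnings.warn(f"dropping zero-variance column {col!r}", stacklevel=2)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=raw.index)


def fragment_signal(tracks: dict[str, SignalTrack], fragments: FragmentMap) -> pd.DataFrame:
    """Per-fragment marker value = mean of the track over the fragment interval."""
    cols = {}
    for name, track in tracks.items():
        vals = np.empty(fragments.n)
        for chrom in fragments.genome.names:
            s = fragments.chrom_slice(chrom)
            vals[s] = track.mean(chrom, fragments.starts[chrom], fragments.ends[chrom])
        cols[name] = vals
    return pd.DataFrame(cols, index=pd.RangeIndex(fragments.n, name="fragment_index"))


def label_fragments(fragments: FragmentMap, centers: BoundarySet) -> np.ndarray:
    """1 for fragments containing a boundary center, 0 otherwise."""
    labels = np.zeros(fragments.n, dtype=np.int8)
    for chrom, pos in centers.per_chrom().items():
        labels[fragments.locate_global(chrom, pos)] = 1
    return labels


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and rank-statistic AUC.

    AUC = (normalised Mann-Whitney U): the probability that a random
    positive scores above a random negative, ties counting 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(fpr, tpr, thr, float(auc))


@dataclass
class BorderModel:
    weights: pd.Series
    intercept: float
    test_index: np.ndarray
    test_scores: np.ndarray
    test_labels: np.ndarray
    roc: ROCResult

    @property
    def auc(self) -> float:
        return self.roc.auc


def fit_border_model(
    features: pd.DataFrame,
    labels,
    split_seed: int = 0,
    balance: bool = True,
    C: float = 100.0,
) -> BorderModel:
    """Fit an L2-regularised logistic regression on a random half of the data
    and score the held-out half.

    With ``balance`` (default), negatives are first subsampled to match
    the positive count (seeded); border fragments are a small minority
    of all fragments, and AUC comparisons are the target. ``C`` is the
    inverse regularisation strength (weak penalty by default, for
    numerical stability on separable data).
    """
    labels = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    idx = np.arange(labels.size)
    pos = idx[labels == 1]
    neg = idx[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if balance and neg.size > pos.size:
        rng = np.random.default_rng(split_seed)
        neg = np.sort(rng.choice(neg, size=pos.size, replace=False))
    keep = np.sort(np.concatenate([pos, neg]))
    train, test = train_test_split(
        keep, test_size=0.5, random_state=split_seed, stratify=labels[keep]
    )
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, tol=1e-8)
    model.fit(X[train], labels[train])
    scores = model.predict_proba(X[test])[:, 1]
    roc = roc_auc(scores, labels[test])
    return BorderModel(
        weights=pd.Series(model.coef_[0], index=features.columns),
        intercept=float(model.intercept_[0]),
        test_index=np.asarray(test),
        test_scores=scores,
        test_labels=labels[test],
        roc=roc,
    )
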