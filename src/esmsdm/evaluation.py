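"""Model evaluation: AUC, Somers' D, TSS, sensitivity, thresholding.

AUC is the rank-based probability that a random presence outscores a
random background point (ties count 1/2). The binarization threshold is
the maximum sensitivity-plus-specificity (max-SSS / TSS-optimum) cutoff,
scanned over the observed scores with ties broken toward the lowest
threshold; presence is score >= threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .raster import Raster

__all__ = [
    "auc",
    "somers_d",
    "tss",
    "sensitivity_at",
    "specificity_at",
    "max_sss_threshold",
    "binarize",
    "occurrences_vs_auc",
]


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise InvalidArgumentError("labels must contain both classes")
    return pos, neg


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def somers_d(auc_value: float) -> float:
    """Somers' D rank-correlation skill score: 2*AUC - 1."""
    if not 0.0 <= auc_value <= 1.0:
        raise InvalidArgumentError("AUC must be in [0, 1]")
    return 2.0 * auc_value - 1.0


def tss(sensitivity: float, specificity: float) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    for v in (sensitivity, specificity):
        if not 0.0 <= v <= 1.0:
            raise InvalidArgumentError("sensitivity/specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def sensitivity_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """Fraction of presences with score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    pos, _ = _check_labels(labels)
    return float(np.mean(scores[pos] >= threshold))


def specificity_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """Fraction of background with score < threshold."""
    scores = np.asarray(scores, dtype=float)
    _, neg = _check_labels(labels)
    return float(np.mean(scores[neg] < threshold))


def max_sss_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max sensitivity-plus-specificity threshold (TSS optimum).

    Candidates are the distinct observed scores; ties broken toward the
    lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    _check_labels(labels)
    best_t, best_sum = None, -np.inf
    for t in np.unique(scores):
        s = sensitivity_at(scores, labels, t) + specificity_at(scores, labels, t)
        if s > best_sum + 1e-12:
            best_t, best_sum = float(t), s
    assert best_t is not None
    return best_t


def binarize(continuous: Raster, threshold: float) -> Raster:
    """Presence/absence map: 1 where value >= threshold, else 0; nodata kept."""
    out = np.where(continuous.data >= threshold, 1.0, 0.0)
    out[~continuous.mask] = np.nan
    return continuous.copy_with(out)


def occurrences_vs_auc(metrics: pd.DataFrame) -> pd.Series:
    """Pearson correlation between occurrence count and AUC, overall and per guild.

    Expects columns ``n_occurrences``, ``auc`` and optionally ``guild``.
    Groups with fewer than 3 species, or zero variance in either
    variable, yield NaN.
    """
    needed = {"n_occurrences", "auc"}
    if not needed <= set(metrics.columns):
        raise InvalidArgumentError(f"metrics table must have columns {needed}")
    d = metrics.dropna(subset=["n_occurrences", "auc"])
    if len(d) < 3:
        raise InvalidArgumentError("need at least 3 species with finite AUC")

    def _r(g: pd.DataFrame) -> float:
        if len(g) < 3 or g["n_occurrences"].std() == 0 or g["auc"].std() == 0:
            return float("nan")
        return float(np.corrcoef(g["n_occurrences"], g["auc"])[0, 1])

    out = {"overall": _r(d)}
    if "guild" in d.columns:
        for guild, g in d.groupby("guild", sort=True):
            out[str(guild)] = _r(g)
    return pd.Series(out, name="pearson_r")
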