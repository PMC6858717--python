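"""Minimal-redundancy-maximal-relevance feature ranking.

Plug-in mutual information (base-2) over empirical discrete joints, with
greedy forward selection: the first feature maximizes relevance to the
label; each later pick maximizes relevance minus mean redundancy against
the already-selected set.  Continuous features are discretized with the
same equal-step rule used for the fatigue labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eyefatigue.config import BLINK_FEATURES, FEATURE_NAMES
from eyefatigue.errors import ValidationError

logger = logging.getLogger(__name__)


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two discrete series, in bits.

    Integer-count arithmetic keeps exactly factorizable joints at exactly
    0 bits.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"series length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n == 0:
        raise ValidationError("empty series")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return mutual_information_from_counts(counts)


def mutual_information_from_counts(counts) -> float:
    """MI in bits from a contingency table of nonnegative integer counts."""
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValidationError("contingency counts must be nonnegative")
    n = int(counts.sum())
    if n == 0:
        raise ValidationError("empty contingency table")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    mi = 0.0
    for i, j in zip(*np.nonzero(counts)):
        c = int(counts[i, j])
        # integer ratio: exactly 1 (hence 0 contribution) under independence
        mi += (c / n) * math.log2((c * n) / (rows[i] * cols[j]))
    return max(mi, 0.0)


def equal_step_bins(values, n_bins: int) -> np.ndarray:
    """Equal-width bin indices over the value range; degenerate range -> all 0."""
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        logger.warning("degenerate feature (zero range); binned as a single level")
        return np.zeros(len(v), dtype=int)
    step = (vmax - vmin) / n_bins
    return np.minimum(np.floor((v - vmin) / step).astype(int), n_bins - 1)


@dataclass
class Ranking:
    """A full feature ordering with per-step selection diagnostics."""

    order: list[str]
    relevance: dict[str, float]  # I(x_i; c) per feature
    step_D: list[float] = field(default_factory=list)  # mean relevance of selected set
    step_R: list[float] = field(default_factory=list)  # mean pairwise redundancy
    step_objective: list[float] = field(default_factory=list)  # greedy pick's score
    n_classes: int = 0

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "relevance": self.relevance,
            "step_D": self.step_D,
            "step_R": self.step_R,
            "step_objective": self.step_objective,
            "n_classes": self.n_classes,
        }


def mrmr_rank(
    features: pd.DataFrame,
    labels,
    n_bins: int | None = None,
    feature_names=None,
) -> Ranking:
    """Greedy MRMR ordering of ``features`` columns against discrete ``labels``.

    Features are discretized into ``n_bins`` equal-step bins (default: the
    number of label classes).  Ties break by column order, which follows the
    canonical feature order when the default columns are used.
    """
    labels = np.asarray(labels)
    names = list(feature_names) if feature_names is not None else list(features.columns)
    if len(labels) != len(features):
        raise ValidationError("labels and features must have equal length")
    n_classes = len(np.unique(labels))
    if n_bins is None:
        n_bins = max(n_classes, 2)
    binned = {name: equal_step_bins(features[name].to_numpy(), n_bins) for name in names}
    relevance = {name: mutual_information(binned[name], labels) for name in names}
    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_information(binned[a], binned[b])
        return pair_mi[key]

    order: list[str] = []
    remaining = list(names)
    ranking = Ranking(order=order, relevance=relevance, n_classes=n_classes)
    while remaining:
        best_name, best_score = None, -np.inf
        for name in remaining:  # iteration order = canonical order = tie-break
            if order:
                red = sum(redundancy(name, s) for s in order) / len(order)
            else:
                red = 0.0
            score = relevance[name] - red
            if score > best_score:
                best_name, best_score = name, score
        order.append(best_name)
        remaining.remove(best_name)
        sel = order
        d = sum(relevance[s] for s in sel) / len(sel)
        r = sum(redundancy(a, b) for a in sel for b in sel) / len(sel) ** 2
        ranking.step_D.append(d)
        ranking.step_R.append(r)
        ranking.step_objective.append(best_score)
    return ranking


def build_feature_sets(ranking: Ranking) -> dict[str, list[str]]:
    """Nested top-k sets from the ranking plus the fixed blink set."""
    if len(ranking.order) != len(FEATURE_NAMES) or set(ranking.order) != set(FEATURE_NAMES):
        raise ValidationError(
            f"ranking must order all {len(FEATURE_NAMES)} features, got {ranking.order}"
        )
    sets = {f"set{k}": ranking.order[:k] for k in range(1, len(FEATURE_NAMES) + 1)}
    sets["blink"] = list(BLINK_FEATURES)
    return sets
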