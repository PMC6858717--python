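"""Weighted optometric eye-fatigue ground truth.

The fatigue score is a weighted sum of the seven optometric indicators,
with each weight the reciprocal of that indicator's mean change between the
first and last measurement over the cohort.  Weight signs therefore follow
the drift direction automatically.  Scores are unified per subject by
subtracting the first-epoch value, and discretized into n equal-width
classes over the whole sample set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from eyefatigue.config import INDICATORS
from eyefatigue.errors import (
    BaselineMissingError,
    DegenerateDataError,
    ValidationError,
)


@dataclass(frozen=True)
class IndicatorWeights:
    """One weight per indicator, in canonical order; units 1/(indicator unit)."""

    values: tuple

    def __post_init__(self):
        if len(self.values) != len(INDICATORS):
            raise ValidationError(
                f"expected {len(INDICATORS)} weights, got {len(self.values)}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(INDICATORS, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[INDICATORS.index(name)]


def _check_panels(panels: pd.DataFrame) -> None:
    missing = [c for c in ("subject", "epoch", *INDICATORS) if c not in panels.columns]
    if missing:
        raise ValidationError(f"optometry table missing columns: {missing}")


def compute_weights(panels: pd.DataFrame, last_epoch: int | None = None) -> IndicatorWeights:
    """Reciprocal mean-change weights from a cohort's panel table.

    ``w_i = 1 / (mean_i(last epoch) - mean_i(epoch 1))``, means over subjects.
    """
    _check_panels(panels)
    if panels["subject"].nunique() < 2:
        raise ValidationError("need at least 2 subjects to compute weights")
    last = int(panels["epoch"].max()) if last_epoch is None else last_epoch
    first_rows = panels[panels["epoch"] == 1]
    last_rows = panels[panels["epoch"] == last]
    if first_rows.empty or last_rows.empty:
        raise ValidationError(f"panels must include epochs 1 and {last}")
    weights = []
    for name in INDICATORS:
        delta = last_rows[name].mean() - first_rows[name].mean()
        if delta == 0.0:
            raise DegenerateDataError(
                f"indicator {name}: epoch-{last} mean equals epoch-1 mean; weight undefined"
            )
        weights.append(1.0 / delta)
    return IndicatorWeights(values=tuple(weights))


def weighted_fatigue(panel, weights: IndicatorWeights) -> float:
    """Weighted fatigue of one panel (mapping or Series with indicator keys)."""
    total = 0.0
    for name, w in zip(INDICATORS, weights.values):
        try:
            v = panel[name]
        except (KeyError, IndexError) as exc:
            raise ValidationError(f"panel missing indicator {name}") from exc
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"panel has missing value for indicator {name}")
        total += w * float(v)
    return total


def unify_series(values, epochs=None) -> np.ndarray:
    """Subtract the first-epoch value from a per-subject series.

    ``values`` is ordered by epoch starting at epoch 1 unless ``epochs`` gives
    explicit epoch numbers.
    """
    v = np.asarray(values, dtype=float)
    if epochs is not None:
        epochs = np.asarray(epochs)
        if 1 not in epochs:
            raise BaselineMissingError("series lacks the epoch-1 baseline")
        base = v[np.flatnonzero(epochs == 1)[0]]
    else:
        if len(v) == 0:
            raise BaselineMissingError("empty series has no baseline")
        base = v[0]
    return v - base


def discretize_labels(values, n: int) -> np.ndarray:
    """Equal-step class labels over the sample set ``values``.

    step = (max - min) / n; label = floor((v - min) / step), clamped to n-1.
    """
    if n < 2:
        raise ValidationError(f"need at least 2 classes, got {n}")
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        raise DegenerateDataError("all values identical; equal-step labels undefined")
    step = (vmax - vmin) / n
    return np.minimum(np.floor((v - vmin) / step).astype(int), n - 1)


def fatigue_table(
    panels: pd.DataFrame,
    weights: IndicatorWeights | None = None,
    classes: tuple[int, ...] = (2, 3, 4),
) -> tuple[pd.DataFrame, IndicatorWeights]:
    """Per subject-epoch fatigue table: F, unified F, and class labels.

    Weights default to being computed from ``panels`` itself; pass frozen
    weights for reproducibility across cohorts.
    """
    _check_panels(panels)
    panels = panels.reset_index(drop=True)
    if weights is None:
        weights = compute_weights(panels)
    df = panels[["subject", "epoch"]].copy()
    w = np.array(weights.values)
    df["F"] = panels[list(INDICATORS)].to_numpy() @ w
    unified = np.empty(len(df))
    for _, idx in df.groupby("subject").groups.items():
        sub = df.loc[idx].sort_values("epoch")
        if int(sub["epoch"].iloc[0]) != 1:
            raise BaselineMissingError(
                f"subject {sub['subject'].iloc[0]}: epoch-1 baseline missing"
            )
        unified[sub.index] = sub["F"].to_numpy() - sub["F"].iloc[0]
    df["F_unified"] = unified
    for n in classes:
        df[f"class{n}"] = discretize_labels(df["F_unified"].to_numpy(), n)
    return df, weights


def indicator_trend_tests(panels: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of each indicator at epochs >= 2 against epoch 1.

    Returns one row per (indicator, epoch) with the paired t-test p-value, a
    p < 0.05 significance flag, and a Kolmogorov-Smirnov normality p-value of
    the standardized paired differences.
    """
    _check_panels(panels)
    wide = panels.pivot_table(index="subject", columns="epoch", values=list(INDICATORS))
    rows = []
    epochs = sorted(panels["epoch"].unique())
    for name in INDICATORS:
        base = wide[(name, 1)].dropna()
        for e in epochs:
            if e == 1:
                continue
            other = wide[(name, e)].dropna()
            paired = pd.concat([base, other], axis=1, join="inner")
            if len(paired) < 2:
                raise ValidationError(
                    f"indicator {name}, epoch {e}: fewer than 2 paired observations"
                )
            diff = paired.iloc[:, 1] - paired.iloc[:, 0]
            t_stat, p = stats.ttest_rel(paired.iloc[:, 1], paired.iloc[:, 0])
            sd = diff.std(ddof=1)
            if sd > 0:
                ks_p = stats.kstest((diff - diff.mean()) / sd, "norm").pvalue
            else:
                ks_p = np.nan
            rows.append(
                {
                    "indicator": name,
                    "epoch": e,
                    "mean_diff": diff.mean(),
                    "t": t_stat,
                    "p_value": p,
                    "significant": bool(p < 0.05),
                    "ks_normality_p": ks_p,
                }
            )
    return pd.DataFrame(rows)


def unweighted_fatigue(panel) -> float:
    """Legacy unweighted score (fixed signs); kept for compatibility only."""
    signs = {"BCC": 1, "PRA": 1, "NRA": -1, "PL": -1, "PR": -1, "LTL": -1, "LTR": -1}
    return float(sum(signs[name] * panel[name] for name in INDICATORS))


def weights_provenance(weights: IndicatorWeights, panels: pd.DataFrame, seed=None) -> dict:
    """JSON-ready weights record with a digest of the source panel table."""
    payload = panels[["subject", "epoch", *INDICATORS]].round(9).to_csv(index=False)
    return {
        "weights": weights.as_dict(),
        "cohort_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "n_subjects": int(panels["subject"].nunique()),
        "seed": seed,
    }


def save_weights(path, weights: IndicatorWeights, panels: pd.DataFrame, seed=None) -> None:
    with open(path, "w") as fh:
        json.dump(weights_provenance(weights, panels, seed), fh, indent=2)


def load_weights(path) -> IndicatorWeights:
    with open(path) as fh:
        d = json.load(fh)["weights"]
    return IndicatorWeights(values=tuple(d[name] for name in INDICATORS))
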