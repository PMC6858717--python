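"""Fixation, blink, and scanpath features from a gaze window.

Fixations come from dispersion-threshold identification (I-DT) over valid
samples: a candidate window spanning the minimum duration qualifies when its
dispersion ``(max x - min x) + (max y - min y)`` stays within the threshold,
grows greedily until dispersion is exceeded, and is emitted with its sample
centroid.  Invalid samples terminate any open window; maximal runs of
invalid samples are blinks.  Saccade lengths are Euclidean distances between
consecutive fixation centroids.

Durations follow a sample-count convention: an event of ``n`` samples at
spacing ``dt`` lasts ``n * dt``, so a fully valid 20-s window yields a 20-s
fixation and blink + fixation time can never exceed the window by more than
one sample period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from eyefatigue.config import FEATURE_NAMES
from eyefatigue.errors import BaselineMissingError, ValidationError
from eyefatigue.synthetic_data.gaze import GazeStream


@dataclass(frozen=True)
class Fixation:
    start: float
    end: float
    duration: float
    centroid_x: float
    centroid_y: float
    n_samples: int


@dataclass(frozen=True)
class Blink:
    start: float
    end: float
    duration: float
    n_samples: int


@dataclass
class DetectorConfig:
    """I-DT and blink detection parameters.

    ``px_per_deg`` converts the angular dispersion threshold to pixels; all
    pixel-valued outputs are generator-relative, so results downstream do not
    hinge on its absolute value.
    """

    min_duration: float = 0.200
    dispersion_deg: float = 1.0
    px_per_deg: float = 10.0
    window_s: float = 20.0
    min_blink_samples: int = 1

    def __post_init__(self):
        if min(self.min_duration, self.dispersion_deg, self.px_per_deg, self.window_s) <= 0:
            raise ValidationError("all detector thresholds must be positive")
        if self.min_blink_samples < 1:
            raise ValidationError("min_blink_samples must be >= 1")

    @property
    def dispersion_px(self) -> float:
        return self.dispersion_deg * self.px_per_deg


@dataclass(frozen=True)
class FeatureVector:
    """The ten gaze features of one window.

    ``VF``/``VB`` are population variances of event durations (s^2); use
    :meth:`sd_fixation`/:meth:`sd_blink` for the SD view.
    """

    NF: float
    DF: float
    MF: float
    VF: float
    BT: float
    DB: float
    MB: float
    VB: float
    SL: float
    ML: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def sd_fixation(self) -> float:
        return math.sqrt(self.VF)

    def sd_blink(self) -> float:
        return math.sqrt(self.VB)


def _sample_interval(t: np.ndarray) -> float:
    if len(t) < 2:
        return 1.0
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        raise ValidationError("gaze timestamps must be strictly increasing")
    return float(np.median(diffs))


def _valid_segments(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal valid runs (stop exclusive)."""
    v = np.asarray(valid, dtype=bool)
    if len(v) == 0:
        return []
    edges = np.flatnonzero(np.diff(v.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(v)]))
    return [
        (int(a), int(b))
        for a, b in zip(bounds[:-1], bounds[1:])
        if v[a]
    ]


def detect_fixations(stream: GazeStream, cfg: DetectorConfig | None = None) -> list[Fixation]:
    """I-DT fixation detection over the valid samples of ``stream``."""
    cfg = cfg or DetectorConfig()
    n = len(stream)
    if n == 0:
        return []
    dt = _sample_interval(stream.t)
    n_min = max(1, int(math.ceil(cfg.min_duration / dt - 1e-9)))
    thresh = cfg.dispersion_px
    fixations: list[Fixation] = []
    xs_all, ys_all, t_all = stream.x, stream.y, stream.t
    for a, b in _valid_segments(stream.valid):
        xs = xs_all[a:b].tolist()
        ys = ys_all[a:b].tolist()
        m = b - a
        i = 0
        while i + n_min <= m:
            seg_x = xs[i : i + n_min]
            seg_y = ys[i : i + n_min]
            mnx, mxx = min(seg_x), max(seg_x)
            mny, mxy = min(seg_y), max(seg_y)
            if (mxx - mnx) + (mxy - mny) > thresh:
                i += 1
                continue
            j = i + n_min - 1
            while j + 1 < m:
                px, py = xs[j + 1], ys[j + 1]
                nmnx = px if px < mnx else mnx
                nmxx = px if px > mxx else mxx
                nmny = py if py < mny else mny
                nmxy = py if py > mxy else mxy
                if (nmxx - nmnx) + (nmxy - nmny) > thresh:
                    break
                mnx, mxx, mny, mxy = nmnx, nmxx, nmny, nmxy
                j += 1
            count = j - i + 1
            fixations.append(
                Fixation(
                    start=float(t_all[a + i]),
                    end=float(t_all[a + i] + count * dt),
                    duration=count * dt,
                    centroid_x=float(np.mean(xs[i : j + 1])),
                    centroid_y=float(np.mean(ys[i : j + 1])),
                    n_samples=count,
                )
            )
            i = j + 1
    return fixations


def detect_blinks(stream: GazeStream, min_blink_samples: int = 1) -> list[Blink]:
    """Maximal runs of invalid samples, one blink each."""
    n = len(stream)
    if n == 0:
        return []
    dt = _sample_interval(stream.t)
    blinks = []
    for a, b in _valid_segments(~stream.valid):
        count = b - a
        if count < min_blink_samples:
            continue
        blinks.append(
            Blink(
                start=float(stream.t[a]),
                end=float(stream.t[a] + count * dt),
                duration=count * dt,
                n_samples=count,
            )
        )
    return blinks


def scanpath_metrics(fixations: list[Fixation]) -> dict[str, float]:
    """Scanpath length ``SL`` (sum) and mean saccade length ``ML``."""
    if len(fixations) < 2:
        return {"SL": 0.0, "ML": 0.0}
    cx = np.array([f.centroid_x for f in fixations])
    cy = np.array([f.centroid_y for f in fixations])
    lengths = np.hypot(np.diff(cx), np.diff(cy))
    return {"SL": float(lengths.sum()), "ML": float(lengths.mean())}


def extract_feature_vector(stream: GazeStream, cfg: DetectorConfig | None = None) -> FeatureVector:
    """The ten-feature vector of one gaze window (truncated to the window)."""
    cfg = cfg or DetectorConfig()
    if len(stream) > 1:
        dt = _sample_interval(stream.t)
        n_keep = int(round(cfg.window_s / dt))
        if len(stream) > n_keep:
            stream = GazeStream(
                t=stream.t[:n_keep],
                x=stream.x[:n_keep],
                y=stream.y[:n_keep],
                valid=stream.valid[:n_keep],
            )
    fixations = detect_fixations(stream, cfg)
    blinks = detect_blinks(stream, cfg.min_blink_samples)
    fd = np.array([f.duration for f in fixations])
    bd = np.array([b.duration for b in blinks])
    sp = scanpath_metrics(fixations)
    nf = len(fixations)
    bt = len(blinks)
    return FeatureVector(
        NF=float(nf),
        DF=float(fd.sum()) if nf else 0.0,
        MF=float(fd.mean()) if nf else 0.0,
        VF=float(fd.var()) if nf else 0.0,
        BT=float(bt),
        DB=float(bd.sum()) if bt else 0.0,
        MB=float(bd.mean()) if bt else 0.0,
        VB=float(bd.var()) if bt else 0.0,
        SL=sp["SL"],
        ML=sp["ML"],
    )


def unify_features(vectors: list[FeatureVector]) -> list[FeatureVector]:
    """Subtract the first-epoch vector componentwise (epoch order assumed)."""
    if not vectors:
        raise BaselineMissingError("no feature vectors to unify")
    base = vectors[0].as_array()
    return [FeatureVector(*(v.as_array() - base)) for v in vectors]


def extract_cohort_features(gaze: dict, cfg: DetectorConfig | None = None) -> pd.DataFrame:
    """Feature table from ``{(subject, epoch): GazeStream}`` windows."""
    cfg = cfg or DetectorConfig()
    rows = []
    for (subject, epoch), stream in sorted(gaze.items()):
        rec = {"subject": subject, "epoch": epoch}
        rec.update(extract_feature_vector(stream, cfg).as_dict())
        rows.append(rec)
    return pd.DataFrame(rows)


def unify_feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per-subject baseline subtraction of every feature column."""
    missing = [c for c in ("subject", "epoch", *FEATURE_NAMES) if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    features = features.reset_index(drop=True)
    out = features.copy()
    for _, idx in features.groupby("subject").groups.items():
        sub = features.loc[idx].sort_values("epoch")
        if int(sub["epoch"].iloc[0]) != 1:
            raise BaselineMissingError(
                f"subject {sub['subject'].iloc[0]}: epoch-1 feature baseline missing"
            )
        base = sub[list(FEATURE_NAMES)].iloc[0]
        out.loc[idx, list(FEATURE_NAMES)] = (
            features.loc[idx, list(FEATURE_NAMES)] - base
        ).to_numpy()
    return out
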