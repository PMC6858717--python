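"""Synthetic 20-s gaze windows as alternating fixation-saccade processes.

A window is assembled from ``n_f`` fixations (stationary dwells with
sub-threshold jitter) separated by instantaneous centroid jumps, with blinks
inserted as maximal runs of invalid samples at fixation boundaries.  The
construction guarantees that a dispersion-threshold detector recovers the
generated fixation count, that maximal-invalid-run blink detection recovers
the generated blink count and durations, and that centroid-to-centroid
saccade lengths recover the sampled amplitudes.  Window-level anchor draws
(fixation count, blink count/duration, saccade amplitude) use moment-matched
lognormals and unbiased stochastic rounding, so grand means converge to the
calibrated targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from eyefatigue.errors import CalibrationError
from eyefatigue.synthetic_data._rand import (
    largest_remainder_alloc,
    lognormal_mean_sd,
    stochastic_round,
)

logger = logging.getLogger(__name__)


@dataclass
class GazeSample:
    """One gaze sample; ``x``/``y`` are NaN when ``valid`` is False."""

    t: float
    x: float
    y: float
    valid: bool


@dataclass
class GazeStream:
    """A time-ordered gaze window: arrays ``t`` (s), ``x``/``y`` (px), ``valid``."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")


@dataclass
class WindowTargets:
    """Window-level anchor targets: (mean, sd) pairs plus blink-duration spread.

    ``vb`` is the within-window variance of blink durations (s^2).
    """

    nf: float
    nf_sd: float
    bt: float
    bt_sd: float
    mb: float
    mb_sd: float
    vb: float
    ml: float
    ml_sd: float
    label: str = ""


def _fixation_positions(
    rng: np.random.Generator,
    n_f: int,
    lengths_px: np.ndarray,
    display_px: tuple[int, int],
    margin: float,
):
    """Random-walk centroids with the requested jump lengths, kept in bounds."""
    w, h = display_px
    corners = ((margin, margin), (w - margin, margin), (margin, h - margin), (w - margin, h - margin))
    pos = np.empty((n_f, 2))
    pos[0] = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
    clamped = 0
    for k in range(1, n_f):
        ln = lengths_px[k - 1]
        px, py = pos[k - 1]
        placed = False
        for _ in range(64):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            qx = px + ln * math.cos(theta)
            qy = py + ln * math.sin(theta)
            if margin <= qx <= w - margin and margin <= qy <= h - margin:
                pos[k] = (qx, qy)
                placed = True
                break
        if not placed:
            # jump longer than any in-bounds direction: head for the farthest
            # corner, which is always at least half the display diagonal away,
            # so the shortened jump still splits fixations cleanly
            fx, fy = max(corners, key=lambda c: (c[0] - px) ** 2 + (c[1] - py) ** 2)
            d = math.hypot(fx - px, fy - py)
            step = min(ln, d)
            pos[k] = (px + step * (fx - px) / d, py + step * (fy - py) / d)
            clamped += 1
    if clamped:
        logger.debug("clamped %d over-long saccades toward the farthest corner", clamped)
    return pos, clamped


def generate_gaze_window(
    targets: WindowTargets,
    window_s: float,
    rate_hz: float,
    rng: np.random.Generator,
    *,
    display_px: tuple[int, int] = (1080, 1200),
    min_fixation_s: float = 0.2,
    jitter_px: float = 1.0,
    min_saccade_px: float = 15.0,
    saccade_cv: float = 0.3,
    gap_samples: int = 2,
    max_retries: int = 200,
) -> GazeStream:
    """Build one gaze window matching the given anchor targets.

    ``min_saccade_px`` keeps jumps safely above a 1-degree dispersion
    threshold at the default 10 px/deg so generated fixations never merge;
    ``gap_samples`` valid samples separate blinks sharing a boundary slot
    (too short to register as a fixation).
    """
    n_total = int(round(window_s * rate_hz))
    dt = 1.0 / rate_hz
    min_fix = max(1, int(math.ceil(min_fixation_s * rate_hz - 1e-9)))

    for _ in range(max_retries):
        n_f = max(1, stochastic_round(rng, lognormal_mean_sd(rng, targets.nf, targets.nf_sd))) if targets.nf > 0 else 1
        n_b = stochastic_round(rng, lognormal_mean_sd(rng, targets.bt, targets.bt_sd)) if targets.bt > 0 else 0
        if n_b > 0:
            mb_w = lognormal_mean_sd(rng, targets.mb, targets.mb_sd)
            durs = lognormal_mean_sd(rng, mb_w, math.sqrt(max(targets.vb, 0.0)), size=n_b)
            blink_samples = np.maximum(1, stochastic_round(rng, np.atleast_1d(durs) * rate_hz))
            slots = np.sort(rng.integers(0, n_f + 1, size=n_b))
        else:
            blink_samples = np.zeros(0, dtype=int)
            slots = np.zeros(0, dtype=int)
        # a valid gap separates blinks that share a slot
        n_gaps = sum(max(0, int(c) - 1) for c in np.bincount(slots, minlength=1)) if n_b else 0
        used = int(blink_samples.sum()) + n_gaps * gap_samples
        if n_f * min_fix + used <= n_total:
            break
    else:
        raise CalibrationError(
            f"infeasible gaze targets {targets.label or targets}: "
            f"cannot fit fixations and blinks into {window_s} s at {rate_hz} Hz"
        )

    extra = n_total - used - n_f * min_fix
    fix_samples = min_fix + largest_remainder_alloc(extra, rng.gamma(2.0, size=n_f))

    if n_f > 1:
        amp_w = max(lognormal_mean_sd(rng, targets.ml, targets.ml_sd), min_saccade_px)
        lengths = np.maximum(
            lognormal_mean_sd(rng, amp_w, saccade_cv * amp_w, size=n_f - 1), min_saccade_px
        )
    else:
        lengths = np.zeros(0)
    margin = max(8.0, 2.0 * jitter_px + 2.0)
    centroids, n_clamped = _fixation_positions(rng, n_f, lengths, display_px, margin)

    # assemble: [slot 0 blinks] fix_1 [slot 1 blinks] ... fix_nf [slot nf blinks]
    x = np.empty(n_total)
    y = np.empty(n_total)
    valid = np.ones(n_total, dtype=bool)
    pos = 0
    blink_by_slot: dict[int, list[int]] = {}
    for s, b in zip(slots, blink_samples):
        blink_by_slot.setdefault(int(s), []).append(int(b))

    def emit_blinks(slot: int, anchor_xy):
        nonlocal pos
        for j, b in enumerate(blink_by_slot.get(slot, ())):
            if j > 0:
                x[pos : pos + gap_samples] = anchor_xy[0]
                y[pos : pos + gap_samples] = anchor_xy[1]
                pos += gap_samples
            x[pos : pos + b] = np.nan
            y[pos : pos + b] = np.nan
            valid[pos : pos + b] = False
            pos += b

    emit_blinks(0, centroids[0])
    for k in range(n_f):
        n = int(fix_samples[k])
        if jitter_px > 0:
            x[pos : pos + n] = centroids[k, 0] + rng.uniform(-jitter_px, jitter_px, n)
            y[pos : pos + n] = centroids[k, 1] + rng.uniform(-jitter_px, jitter_px, n)
        else:
            x[pos : pos + n] = centroids[k, 0]
            y[pos : pos + n] = centroids[k, 1]
        pos += n
        anchor = centroids[min(k + 1, n_f - 1)]
        emit_blinks(k + 1, anchor)
    assert pos == n_total, "window assembly must fill the sample budget exactly"

    t = np.arange(n_total) * dt
    meta = {
        "n_fixations": int(n_f),
        "n_blinks": int(n_b),
        "blink_samples": blink_samples.tolist(),
        "fixation_samples": fix_samples.tolist(),
        "saccade_lengths": lengths.tolist(),
        "centroids": centroids.tolist(),
        "clamped_saccades": int(n_clamped),
        "rate_hz": rate_hz,
    }
    return GazeStream(t=t, x=x, y=y, valid=valid, meta=meta)
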