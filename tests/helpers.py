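"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles (exhaustive interval
checks, direct summation) without sharing code paths with the package
implementations they verify.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_dispersion(x, y) -> float:
    return (max(x) - min(x)) + (max(y) - min(y))


def oracle_fixations(t, x, y, valid, min_duration: float, threshold: float):
    """Exhaustive greedy fixation search.

    At every candidate start inside a maximal valid run, the minimum-duration
    interval is tested by recomputing its dispersion from scratch; qualifying
    intervals are extended sample by sample (again recomputing dispersion in
    full) until dispersion is exceeded, then emitted.  Returns a list of
    (start_index, end_index_inclusive) pairs.
    """
    t = np.asarray(t, dtype=float)
    diffs = np.diff(t)
    dt = float(np.median(diffs)) if len(diffs) else 1.0
    n_min = max(1, int(math.ceil(min_duration / dt - 1e-9)))
    valid = np.asarray(valid, dtype=bool)
    n = len(t)
    out = []
    seg_start = None
    segments = []
    for i in range(n + 1):
        if i < n and valid[i]:
            if seg_start is None:
                seg_start = i
        else:
            if seg_start is not None:
                segments.append((seg_start, i))
                seg_start = None
    for a, b in segments:
        i = a
        while i + n_min <= b:
            if oracle_dispersion(x[i : i + n_min], y[i : i + n_min]) > threshold:
                i += 1
                continue
            j = i + n_min - 1
            while j + 1 < b and oracle_dispersion(x[i : j + 2], y[i : j + 2]) <= threshold:
                j += 1
            out.append((i, j))
            i = j + 1
    return out


def oracle_blinks(valid):
    """Maximal invalid runs as (start_index, end_index_inclusive) pairs."""
    valid = np.asarray(valid, dtype=bool)
    out = []
    start = None
    for i in range(len(valid) + 1):
        if i < len(valid) and not valid[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                out.append((start, i - 1))
                start = None
    return out


def oracle_mi_bits(counts) -> float:
    """Term-by-term plug-in mutual information from a contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / n
            if p > 0:
                mi += p * math.log2(p / (px[i] * py[j]))
    return mi


def random_gaze_arrays(rng, n_samples: int, rate_hz: float = 75.0, cluster_px: float = 3.0):
    """A random stream mixing stationary clusters, drifts, and invalid runs."""
    t = np.arange(n_samples) / rate_hz
    x = np.empty(n_samples)
    y = np.empty(n_samples)
    valid = np.ones(n_samples, dtype=bool)
    pos = rng.uniform(100, 900, size=2)
    i = 0
    while i < n_samples:
        kind = rng.choice(["dwell", "move", "blink"], p=[0.5, 0.3, 0.2])
        run = int(rng.integers(3, 40))
        run = min(run, n_samples - i)
        if kind == "dwell":
            x[i : i + run] = pos[0] + rng.uniform(-cluster_px, cluster_px, run)
            y[i : i + run] = pos[1] + rng.uniform(-cluster_px, cluster_px, run)
        elif kind == "move":
            tgt = rng.uniform(50, 1000, size=2)
            x[i : i + run] = np.linspace(pos[0], tgt[0], run)
            y[i : i + run] = np.linspace(pos[1], tgt[1], run)
            pos = tgt
        else:
            x[i : i + run] = np.nan
            y[i : i + run] = np.nan
            valid[i : i + run] = False
        if kind == "dwell" and rng.random() < 0.5:
            pos = rng.uniform(50, 1000, size=2)
        i += run
    return t, x, y, valid
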