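"""Small sampling helpers shared by the generators."""

from __future__ import annotations

import math

import numpy as np


def lognormal_mean_sd(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Draw lognormal variates with the given arithmetic mean and SD.

    Positive support with an exactly matched first moment, so calibrated
    means survive truncation-free.  ``sd <= 0`` degenerates to the constant
    ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be > 0, got {mean}")
    if sd <= 0:
        return mean if size is None else np.full(size, float(mean))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def stochastic_round(rng: np.random.Generator, x) -> np.ndarray | int:
    """Round to an integer without bias: floor(x) + Bernoulli(frac(x))."""
    x = np.asarray(x, dtype=float)
    lo = np.floor(x)
    out = (lo + (rng.random(x.shape) < (x - lo))).astype(int)
    return int(out) if out.shape == () else out


def largest_remainder_alloc(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` integer units proportionally to ``weights`` (sum exact)."""
    if total <= 0:
        return np.zeros(len(weights), dtype=int)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base
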