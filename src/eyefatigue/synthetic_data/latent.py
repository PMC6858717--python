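"""Latent per-subject fatigue trajectories.

Each subject carries a positive susceptibility multiplier (mean 1) and each
epoch adds independent noise.  The active arm ramps linearly from 0 at the
first epoch to 1 at the last in expectation; the control arm stays at 0.
Indicator- and feature-specific drift shapes are layered on top of this
shared trajectory by the per-quantity generators.
"""

from __future__ import annotations

import numpy as np

from eyefatigue.config import CohortConfig


def epoch_ramp(epochs: int, arm: str) -> np.ndarray:
    """Expected latent fatigue per epoch: 0 -> 1 (main) or all zero (control)."""
    if arm == "control":
        return np.zeros(epochs)
    return np.linspace(0.0, 1.0, epochs)


def sample_susceptibility(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Per-subject susceptibility, gamma with mean exactly 1 and SD ``sd``."""
    if sd <= 0:
        return np.ones(n)
    shape = 1.0 / sd**2
    return rng.gamma(shape, scale=1.0 / shape, size=n)


def sample_latent(config: CohortConfig, rng: np.random.Generator):
    """Return (f, susceptibility, ramp).

    ``f`` has shape (n_subjects, epochs); ``E[f[:, e]] == ramp[e]`` exactly.
    """
    ramp = epoch_ramp(config.epochs, config.arm)
    susc = sample_susceptibility(rng, config.n_subjects, config.susceptibility_sd)
    noise = rng.normal(0.0, config.latent_noise_sd, size=(config.n_subjects, config.epochs))
    f = susc[:, None] * ramp[None, :] + noise
    return f, susc, ramp


def latent_variance(config: CohortConfig, ramp: np.ndarray) -> np.ndarray:
    """Per-epoch variance of the latent scalar across subjects."""
    return ramp**2 * config.susceptibility_sd**2 + config.latent_noise_sd**2
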