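"""Synthetic optometry panels calibrated to per-epoch (mean, SD) targets.

Each indicator follows its own drift shape between the first- and last-epoch
calibrated means; a subject's position along that drift is modulated by the
shared latent fatigue trajectory.  Population means per epoch match the
calibration exactly in expectation for any linkage strength, because the
latent term enters mean-centered.
"""

from __future__ import annotations

import numpy as np

from eyefatigue.config import INDICATORS, CohortConfig
from eyefatigue.errors import ConfigurationError
from eyefatigue.synthetic_data.latent import epoch_ramp, latent_variance

#: Indicators that must stay strictly positive (physical diameters/thicknesses).
_POSITIVE = ("PR", "PL", "LTR", "LTL")
#: Phoropter readings on the 0.25-D instrument grid (optional quantization).
_DIOPTER_GRID = ("BCC", "NRA", "PRA")


def drift_params(calibration, names, epochs: int, ramp: np.ndarray):
    """Return (means, slopes) arrays of shape (epochs, len(names)).

    ``slopes[e, i]`` is the latent-to-quantity gain at epoch ``e`` such that
    baseline + slope * ramp reproduces the calibrated epoch mean exactly.
    """
    means = np.empty((epochs, len(names)))
    slopes = np.empty_like(means)
    for i, name in enumerate(names):
        rows = calibration[name]
        m = np.array([rows[e][0] for e in range(epochs)])
        means[:, i] = m
        delta = m[-1] - m[0]
        shape = np.ones(epochs)
        if delta != 0.0:
            # normalized drift shape; where the ramp is 0 the centered latent
            # term has zero mean anyway, so the unit gain is a free choice
            nz = ramp > 0
            shape[nz] = ((m[nz] - m[0]) / delta) / ramp[nz]
        slopes[:, i] = delta * shape
    return means, slopes


def _epoch_params(calibration, epochs: int, ramp: np.ndarray):
    return drift_params(calibration, INDICATORS, epochs, ramp)


def residual_sd(calibration, names, epochs: int, slopes, linkage, lat_var: np.ndarray, floor_frac: float = 0.0):
    """Residual noise SD so the total cross-sectional SD matches calibration.

    ``linkage`` may be a scalar or per-name array; ``floor_frac`` keeps at
    least that fraction of the calibrated SD as residual spread.
    """
    sds = np.empty((epochs, len(names)))
    for i, name in enumerate(names):
        sds[:, i] = [calibration[name][e][1] for e in range(epochs)]
    structured = (slopes * np.asarray(linkage)) ** 2 * lat_var[:, None]
    return np.sqrt(np.maximum(sds**2 - structured, (floor_frac * sds) ** 2))


def _noise_sd(calibration, epochs: int, slopes, linkage: float, lat_var: np.ndarray):
    return residual_sd(calibration, INDICATORS, epochs, slopes, linkage, lat_var)


def generate_optometry_cohort(
    config: CohortConfig, f: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Panels for a whole cohort, shape (n_subjects, epochs, 7).

    ``f`` is the latent fatigue matrix from :func:`sample_latent`.
    """
    ramp = epoch_ramp(config.epochs, config.arm)
    means, slopes = _epoch_params(config.optometry_calibration, config.epochs, ramp)
    lat_var = latent_variance(config, ramp)
    kappa = config.linkage_optometry
    noise_sd = _noise_sd(config.optometry_calibration, config.epochs, slopes, kappa, lat_var)

    rho = config.intercept_share
    intercept = rng.normal(size=(config.n_subjects, 1, len(INDICATORS)))
    eps = rng.normal(size=(config.n_subjects, config.epochs, len(INDICATORS)))
    noise = noise_sd[None] * (np.sqrt(rho) * intercept + np.sqrt(1.0 - rho) * eps)

    centered = f - ramp[None, :]
    x = means[None] + kappa * slopes[None] * centered[:, :, None] + noise

    for i, name in enumerate(INDICATORS):
        if name in _POSITIVE:
            np.clip(x[:, :, i], 0.05, None, out=x[:, :, i])
    if config.quantize_diopters:
        for i, name in enumerate(INDICATORS):
            if name in _DIOPTER_GRID:
                x[:, :, i] = np.round(x[:, :, i] / 0.25) * 0.25
    return x


def generate_optometry_series(
    trajectory,
    calibration,
    rng: np.random.Generator,
    *,
    linkage: float = 1.0,
    noise_scale: float = 1.0,
    susceptibility_sd: float = 0.3,
    latent_noise_sd: float = 0.1,
    arm: str = "main",
) -> np.ndarray:
    """Panels for one subject from an explicit latent trajectory.

    Returns an (epochs, 7) array in :data:`INDICATORS` order.  With an
    all-zero trajectory, ``noise_scale=0`` and ``linkage=1``, every epoch
    reproduces the first-epoch calibrated means (no-drift identity).
    """
    traj = np.asarray(trajectory, dtype=float)
    epochs = len(traj)
    if epochs < 2:
        raise ConfigurationError("trajectory must cover at least 2 epochs")
    ramp = epoch_ramp(epochs, arm)
    means, slopes = _epoch_params(calibration, epochs, ramp)
    lat_var = ramp**2 * susceptibility_sd**2 + latent_noise_sd**2
    noise_sd = _noise_sd(calibration, epochs, slopes, linkage, lat_var) * noise_scale
    # main arm: baseline + slope * trajectory (epoch means re-emerge when the
    # trajectory sits on the ramp); control arm: calibrated means directly
    base = means[0][None, :] if arm == "main" else means
    x = (
        base
        + linkage * slopes * traj[:, None]
        + noise_sd * rng.normal(size=(epochs, len(INDICATORS)))
    )
    for i, name in enumerate(INDICATORS):
        if name in _POSITIVE:
            np.clip(x[:, i], 0.05, None, out=x[:, i])
    return x


def indicator_slopes(calibration, epochs: int = 4, arm: str = "main") -> dict[str, float]:
    """End-to-end drift gain per indicator (sign = drift direction)."""
    ramp = epoch_ramp(epochs, arm)
    _, slopes = _epoch_params(calibration, epochs, ramp)
    return {name: float(slopes[-1, i]) for i, name in enumerate(INDICATORS)}
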