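"""Cohort configuration and default calibration constants.

The default calibration encodes the per-epoch population mean and SD of the
seven optometric indicators (both study arms) and of the gaze-window event
statistics used as generator anchors.  Means drive the synthetic drift; SDs
set between-subject/between-window spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from eyefatigue.errors import ConfigurationError

#: The seven optometric indicators, in the canonical weighting order.
INDICATORS = ("BCC", "NRA", "PRA", "PR", "PL", "LTR", "LTL")

#: The ten gaze features, in canonical order (used for deterministic tie-breaks).
FEATURE_NAMES = ("NF", "DF", "MF", "VF", "BT", "DB", "MB", "VB", "SL", "ML")

#: The four blink-derived features.
BLINK_FEATURES = ("BT", "DB", "MB", "VB")

# (mean, sd) per epoch 1..4, active-viewing arm.
OPTOMETRY_CALIBRATION_MAIN: dict[str, tuple[tuple[float, float], ...]] = {
    "BCC": ((0.14, 0.08), (0.26, 0.34), (0.36, 0.36), (0.50, 0.40)),
    "NRA": ((2.35, 0.60), (2.15, 0.61), (2.00, 0.62), (1.79, 0.64)),
    "PRA": ((-2.74, 1.55), (-2.40, 1.50), (-2.11, 1.40), (-1.78, 1.33)),
    "PR": ((5.37, 0.62), (5.21, 0.60), (5.08, 0.60), (4.93, 0.62)),
    "PL": ((5.29, 0.67), (5.10, 0.63), (4.95, 0.65), (4.79, 0.65)),
    "LTR": ((3.95, 0.36), (3.90, 0.36), (3.86, 0.36), (3.79, 0.36)),
    "LTL": ((3.95, 0.35), (3.89, 0.35), (3.86, 0.36), (3.77, 0.35)),
}

# (mean, sd) per epoch 1..4, eyes-closed control arm (stationary by design).
OPTOMETRY_CALIBRATION_CONTROL: dict[str, tuple[tuple[float, float], ...]] = {
    "BCC": ((0.14, 0.28), (0.14, 0.28), (0.14, 0.28), (0.14, 0.28)),
    "NRA": ((2.35, 0.60), (2.35, 0.60), (2.35, 0.60), (2.35, 0.60)),
    "PRA": ((-2.74, 1.55), (-2.74, 1.55), (-2.74, 1.55), (-2.74, 1.55)),
    "PR": ((5.37, 0.62), (5.37, 0.62), (5.37, 0.61), (5.37, 0.62)),
    "PL": ((5.29, 0.67), (5.29, 0.67), (5.29, 0.66), (5.29, 0.68)),
    "LTR": ((3.95, 0.36), (3.95, 0.36), (3.94, 0.36), (3.95, 0.36)),
    "LTL": ((3.94, 0.35), (3.95, 0.35), (3.95, 0.35), (3.95, 0.36)),
}

# Gaze-window generator anchors, (mean, sd) per epoch 1..4, active arm.
# NF: fixation count; BT: blink count; MB: mean blink duration (s);
# VB: within-window blink-duration variance (s^2); ML: mean saccade length (px).
GAZE_CALIBRATION_MAIN: dict[str, tuple[tuple[float, float], ...]] = {
    "NF": ((43.12, 7.97), (39.50, 8.20), (35.62, 8.98), (30.19, 9.61)),
    "BT": ((2.57, 2.44), (4.65, 3.51), (6.79, 4.50), (10.21, 6.18)),
    "MB": ((0.16, 0.07), (0.20, 0.03), (0.21, 0.04), (0.25, 0.07)),
    "VB": (
        (4.01e-4, 3.05e-4),
        (1.13e-3, 1.06e-3),
        (2.71e-3, 2.16e-3),
        (1.06e-2, 0.87e-2),
    ),
    "ML": ((137.11, 84.5), (209.91, 110.03), (331.59, 255.29), (619.30, 500.48)),
}

# Control-arm gaze windows are stationary: first-epoch anchors at every epoch.
GAZE_CALIBRATION_CONTROL: dict[str, tuple[tuple[float, float], ...]] = {
    name: (rows[0],) * 4 for name, rows in GAZE_CALIBRATION_MAIN.items()
}

# Reference per-epoch (mean, sd) for the emergent features (not generator
# anchors; documented for reporting/trend expectations only).
FEATURE_REFERENCE_MAIN: dict[str, tuple[tuple[float, float], ...]] = {
    "DF": ((16.97, 0.56), (16.88, 0.87), (16.72, 1.08), (16.05, 1.75)),
    "MF": ((0.41, 0.12), (0.46, 0.15), (0.53, 0.29), (0.67, 0.57)),
    "VF": ((0.08, 0.06), (0.13, 0.09), (0.40, 0.31), (0.91, 0.63)),
    "DB": ((0.49, 0.49), (0.95, 0.77), (1.48, 1.05), (2.55, 1.73)),
    "SL": (
        (6002.49, 3994.3),
        (8387.62, 4824.81),
        (11109.34, 6576.00),
        (16063.95, 8713.61),
    ),
}

#: Default per-anchor latent-linkage strengths (dimensionless).  The linkage
#: scales how strongly a subject's latent fatigue modulates the anchor around
#: its epoch mean; 0 decouples an anchor from the latent trajectory.
DEFAULT_GAZE_LINKAGE = {"NF": 0.7, "BT": 0.7, "MB": 0.7, "ML": 0.7}


def _normalize_calibration(raw: Mapping, names: Sequence[str], epochs: int, what: str):
    """Validate and coerce a calibration mapping to {name: ((m, sd), ...)}."""
    out = {}
    for name in names:
        if name not in raw:
            raise ConfigurationError(f"{what} calibration missing entry for {name!r}")
        rows = tuple((float(m), float(s)) for m, s in raw[name])
        if len(rows) < epochs:
            raise ConfigurationError(
                f"{what} calibration for {name!r} has {len(rows)} epochs, need {epochs}"
            )
        for e, (_, s) in enumerate(rows, start=1):
            if s < 0:
                raise ConfigurationError(
                    f"{what} calibration for {name!r}, epoch {e}: negative SD {s}"
                )
        out[name] = rows
    return out


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    Attributes
    ----------
    n_subjects, epochs : cohort shape (105 subjects x 4 measurement epochs).
    window_s, rate_hz : gaze analysis window length and sampling rate.
    arm : ``"main"`` (active HMD viewing) or ``"control"`` (stationary).
    seed : master seed; every random draw derives from it.
    optometry_calibration, gaze_calibration : per-epoch (mean, sd) tables;
        ``None`` selects the built-in defaults for the chosen arm.
    latent_noise_sd : SD of the per-epoch noise on the latent fatigue scalar.
    susceptibility_sd : SD of the per-subject susceptibility multiplier
        (mean 1, gamma-distributed).
    linkage_optometry : how strongly latent fatigue modulates the optometric
        indicators around their epoch means.
    linkage_gaze : per-anchor latent-linkage strengths for gaze anchors.
    intercept_share : fraction of optometric indicator variance attributed to
        a stable per-subject intercept (makes repeat measurements of one
        subject correlated, as instrument panels are in practice).
    quantize_diopters : round BCC/NRA/PRA to the 0.25-D instrument grid.
        Off by default: quantizing biases narrow-SD epoch means by up to
        ~0.01 D, which would defeat exact mean calibration.
    display_px : usable panel geometry (one eye) for gaze positions.
    """

    n_subjects: int = 105
    epochs: int = 4
    window_s: float = 20.0
    rate_hz: float = 75.0
    arm: str = "main"
    seed: int = 0
    optometry_calibration: dict | None = None
    gaze_calibration: dict | None = None
    latent_noise_sd: float = 0.1
    susceptibility_sd: float = 0.3
    linkage_optometry: float = 0.5
    linkage_gaze: dict = field(default_factory=lambda: dict(DEFAULT_GAZE_LINKAGE))
    intercept_share: float = 0.9
    quantize_diopters: bool = False
    display_px: tuple[int, int] = (1080, 1200)

    def __post_init__(self):
        if self.arm not in ("main", "control"):
            raise ConfigurationError(f"arm must be 'main' or 'control', got {self.arm!r}")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.epochs < 2:
            raise ConfigurationError("epochs must be >= 2")
        if self.rate_hz <= 0:
            raise ConfigurationError("rate_hz must be > 0")
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be > 0")
        if not 0.0 <= self.intercept_share <= 1.0:
            raise ConfigurationError("intercept_share must be in [0, 1]")
        if self.latent_noise_sd < 0 or self.susceptibility_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.optometry_calibration is None:
            self.optometry_calibration = (
                OPTOMETRY_CALIBRATION_MAIN
                if self.arm == "main"
                else OPTOMETRY_CALIBRATION_CONTROL
            )
        if self.gaze_calibration is None:
            self.gaze_calibration = (
                GAZE_CALIBRATION_MAIN if self.arm == "main" else GAZE_CALIBRATION_CONTROL
            )
        self.optometry_calibration = _normalize_calibration(
            self.optometry_calibration, INDICATORS, self.epochs, "optometry"
        )
        self.gaze_calibration = _normalize_calibration(
            self.gaze_calibration, tuple(DEFAULT_GAZE_LINKAGE) + ("VB",), self.epochs, "gaze"
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["display_px"] = list(self.display_px)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "display_px" in d:
            d["display_px"] = tuple(d["display_px"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
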