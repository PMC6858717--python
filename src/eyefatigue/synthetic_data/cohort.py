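"""Seeded assembly of a full synthetic cohort.

One master seed deterministically derives independent child streams for the
latent trajectories, optometry panels, gaze windows, and SSQ responses, so
any fixed configuration reproduces byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eyefatigue.config import INDICATORS, CohortConfig
from eyefatigue.ssq_scoring import SSQ_ITEMS
from eyefatigue.synthetic_data.gaze import GazeStream, WindowTargets, generate_gaze_window
from eyefatigue.synthetic_data.latent import epoch_ramp, latent_variance, sample_latent
from eyefatigue.synthetic_data.optometry import (
    drift_params,
    generate_optometry_cohort,
    residual_sd,
)
from eyefatigue.synthetic_data.ssq_gen import generate_ssq_responses

#: Gaze anchors with (mean, sd) drift calibration; VB is handled separately.
_ANCHORS = ("NF", "BT", "MB", "ML")


@dataclass
class Cohort:
    """A generated cohort: panels, gaze windows, SSQ responses, latent truth."""

    config: CohortConfig
    latent: np.ndarray  # (n_subjects, epochs)
    susceptibility: np.ndarray  # (n_subjects,)
    optometry: pd.DataFrame  # subject, epoch, arm, BCC..LTL
    gaze: dict = field(default_factory=dict)  # (subject, epoch) -> GazeStream
    ssq: pd.DataFrame | None = None  # subject, epoch, item_1..item_16

    @property
    def n_subjects(self) -> int:
        return self.config.n_subjects

    @property
    def epochs(self) -> int:
        return self.config.epochs


def window_targets(
    config: CohortConfig, f_value: float, epoch: int, *, label: str = ""
) -> WindowTargets:
    """Anchor targets for one subject-epoch window given its latent value.

    The latent deviation from the expected epoch ramp shifts each anchor mean
    along its drift slope (scaled by the per-anchor linkage); residual spread
    is reduced accordingly so the cross-window SD stays on calibration.
    """
    ramp = epoch_ramp(config.epochs, config.arm)
    means, slopes = drift_params(config.gaze_calibration, _ANCHORS, config.epochs, ramp)
    kappa = np.array([config.linkage_gaze.get(a, 0.0) for a in _ANCHORS])
    lat_var = latent_variance(config, ramp)
    resid = residual_sd(
        config.gaze_calibration, _ANCHORS, config.epochs, slopes, kappa, lat_var, floor_frac=0.3
    )
    e = epoch - 1
    dev = f_value - ramp[e]
    mu = means[e] + slopes[e] * kappa * dev
    mu = np.maximum(mu, 0.02 * np.abs(means[e]) + 1e-6)
    nf, bt, mb, ml = mu
    vb = config.gaze_calibration["VB"][e][0]
    return WindowTargets(
        nf=nf,
        nf_sd=resid[e, 0],
        bt=bt,
        bt_sd=resid[e, 1],
        mb=mb,
        mb_sd=resid[e, 2],
        vb=vb,
        ml=ml,
        ml_sd=resid[e, 3],
        label=label or f"epoch {epoch}",
    )


def epoch_window_targets(config: CohortConfig, epoch: int) -> WindowTargets:
    """Population-level anchor targets for an epoch (latent on the ramp)."""
    ramp = epoch_ramp(config.epochs, config.arm)
    return window_targets(config, float(ramp[epoch - 1]), epoch)


def generate_cohort(
    config: CohortConfig, *, include_gaze: bool = True, include_ssq: bool = True
) -> Cohort:
    """Generate the full cohort bundle for ``config`` (deterministic in seed)."""
    ss = np.random.SeedSequence(config.seed)
    ss_latent, ss_opto, ss_gaze, ss_ssq = ss.spawn(4)

    f, susc, _ = sample_latent(config, np.random.default_rng(ss_latent))

    panels = generate_optometry_cohort(config, f, np.random.default_rng(ss_opto))
    records = []
    for s in range(config.n_subjects):
        for e in range(config.epochs):
            rec = {"subject": s + 1, "epoch": e + 1, "arm": config.arm}
            rec.update({name: panels[s, e, i] for i, name in enumerate(INDICATORS)})
            records.append(rec)
    opto_df = pd.DataFrame(records)

    gaze: dict[tuple[int, int], GazeStream] = {}
    if include_gaze:
        children = ss_gaze.spawn(config.n_subjects * config.epochs)
        k = 0
        for s in range(config.n_subjects):
            for e in range(config.epochs):
                tgt = window_targets(
                    config, float(f[s, e]), e + 1, label=f"subject {s + 1}, epoch {e + 1}"
                )
                gaze[(s + 1, e + 1)] = generate_gaze_window(
                    tgt,
                    config.window_s,
                    config.rate_hz,
                    np.random.default_rng(children[k]),
                    display_px=config.display_px,
                )
                k += 1

    ssq_df = None
    if include_ssq:
        scores = generate_ssq_responses(f, np.random.default_rng(ss_ssq))
        rows = []
        for s in range(config.n_subjects):
            for e in range(config.epochs):
                row = {"subject": s + 1, "epoch": e + 1}
                row.update(
                    {f"item_{i + 1}": int(scores[s, e, i]) for i in range(len(SSQ_ITEMS))}
                )
                rows.append(row)
        ssq_df = pd.DataFrame(rows)

    return Cohort(
        config=config,
        latent=f,
        susceptibility=susc,
        optometry=opto_df,
        gaze=gaze,
        ssq=ssq_df,
    )
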