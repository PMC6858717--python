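"""End-to-end orchestration: simulate -> score -> label -> extract -> rank ->
evaluate -> fit the two assessment bundles, with a reproducibility manifest.

A master seed derives fixed child seeds for the control-arm cohort and the
evaluation protocol, so a rerun with the same configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from eyefatigue import __version__, io
from eyefatigue.assessment import EvalProtocol, evaluate_grid, fit_assessment_model
from eyefatigue.config import FEATURE_NAMES, INDICATORS, CohortConfig
from eyefatigue.gaze_features import (
    DetectorConfig,
    extract_cohort_features,
    unify_feature_table,
)
from eyefatigue.ground_truth import fatigue_table, indicator_trend_tests, save_weights
from eyefatigue.mrmr import mrmr_rank
from eyefatigue.ssq_scoring import score_ssq_table
from eyefatigue.synthetic_data import generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Config snapshot, derived seeds, file digests, and stage timings."""

    config: dict
    seed: int
    version: str = __version__
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    stages: list = field(default_factory=list)  # (stage, seconds)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, path: Path) -> None:
    manifest.outputs[path.name] = _digest(path)


def _scaled_protocol(n_samples: int, rounds: int, seed: int) -> EvalProtocol:
    """320/100 at the default 420 samples; proportional otherwise."""
    test_n = max(2, int(round(n_samples * 100 / 420)))
    return EvalProtocol(train_n=n_samples - test_n, test_n=test_n, rounds=rounds, seed=seed)


def feature_trend_tests(features: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of every gaze feature at epochs >= 2 against epoch 1."""
    from scipy import stats

    rows = []
    wide = features.pivot_table(index="subject", columns="epoch", values=list(FEATURE_NAMES))
    for name in FEATURE_NAMES:
        base = wide[(name, 1)]
        for e in sorted(features["epoch"].unique()):
            if e == 1:
                continue
            diff = wide[(name, e)] - base
            t_stat, p = stats.ttest_rel(wide[(name, e)], base)
            rows.append(
                {
                    "feature": name,
                    "epoch": e,
                    "mean_diff": diff.mean(),
                    "t": t_stat,
                    "p_value": p,
                    "significant": bool(p < 0.05),
                }
            )
    return pd.DataFrame(rows)


def summary_table(df: pd.DataFrame, value_cols) -> pd.DataFrame:
    """Mean +/- SD per epoch for each column (cohort summary layout)."""
    rows = []
    for name in value_cols:
        rec = {"quantity": name}
        for e in sorted(df["epoch"].unique()):
            vals = df.loc[df["epoch"] == e, name]
            rec[f"epoch{e}_mean"] = vals.mean()
            rec[f"epoch{e}_sd"] = vals.std(ddof=1)
        rows.append(rec)
    return pd.DataFrame(rows)


def run_experiment(
    config: CohortConfig,
    outdir,
    *,
    rounds: int = 100,
    detector: DetectorConfig | None = None,
    write_gaze: bool = False,
    arms=("main", "control"),
) -> RunManifest:
    """Run every pipeline stage and write machine-readable outputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    detector = detector or DetectorConfig(window_s=config.window_s)
    ss = np.random.SeedSequence(config.seed)
    control_seed, eval_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        stage_seeds={"main": config.seed, "control": control_seed, "evaluation": eval_seed},
    )
    config.to_yaml(outdir / "config.yaml")
    _register(manifest, outdir / "config.yaml")

    cohorts = {}
    for arm in arms:
        t0 = time.perf_counter()
        arm_cfg = dataclasses.replace(
            config,
            arm=arm,
            seed=config.seed if arm == "main" else control_seed,
            optometry_calibration=None,
            gaze_calibration=None,
        )
        cohort = generate_cohort(arm_cfg, include_gaze=(arm == "main"))
        cohorts[arm] = cohort
        io.write_optometry_csv(cohort.optometry, outdir / f"optometry_{arm}.csv")
        _register(manifest, outdir / f"optometry_{arm}.csv")
        io.write_ssq_csv(cohort.ssq, outdir / f"ssq_{arm}.csv")
        _register(manifest, outdir / f"ssq_{arm}.csv")
        scores = score_ssq_table(cohort.ssq)
        scores.to_csv(outdir / f"ssq_scores_{arm}.csv", index=False)
        _register(manifest, outdir / f"ssq_scores_{arm}.csv")
        trends = indicator_trend_tests(cohort.optometry)
        trends.to_csv(outdir / f"trends_optometry_{arm}.csv", index=False)
        _register(manifest, outdir / f"trends_optometry_{arm}.csv")
        summary_table(cohort.optometry, INDICATORS).to_csv(
            outdir / f"summary_optometry_{arm}.csv", index=False
        )
        _register(manifest, outdir / f"summary_optometry_{arm}.csv")
        if write_gaze and cohort.gaze:
            io.write_gaze_dir(cohort.gaze, outdir / f"gaze_{arm}")
        manifest.stages.append((f"simulate_{arm}", round(time.perf_counter() - t0, 3)))

    main = cohorts["main"]

    t0 = time.perf_counter()
    fatigue, weights = fatigue_table(main.optometry)
    fatigue.to_csv(outdir / "fatigue_main.csv", index=False)
    _register(manifest, outdir / "fatigue_main.csv")
    save_weights(outdir / "weights.json", weights, main.optometry, seed=config.seed)
    _register(manifest, outdir / "weights.json")
    manifest.stages.append(("ground_truth", round(time.perf_counter() - t0, 3)))

    t0 = time.perf_counter()
    features = extract_cohort_features(main.gaze, detector)
    io.write_features_csv(features, outdir / "features_main.csv")
    _register(manifest, outdir / "features_main.csv")
    unified = unify_feature_table(features)
    io.write_features_csv(unified, outdir / "features_unified_main.csv")
    _register(manifest, outdir / "features_unified_main.csv")
    with open(outdir / "detector.json", "w") as fh:
        json.dump(dataclasses.asdict(detector), fh, indent=2)
    _register(manifest, outdir / "detector.json")
    feature_trend_tests(features).to_csv(outdir / "trends_features_main.csv", index=False)
    _register(manifest, outdir / "trends_features_main.csv")
    summary_table(features, FEATURE_NAMES).to_csv(
        outdir / "summary_features_main.csv", index=False
    )
    _register(manifest, outdir / "summary_features_main.csv")
    manifest.stages.append(("features", round(time.perf_counter() - t0, 3)))

    t0 = time.perf_counter()
    merged = unified.merge(fatigue, on=["subject", "epoch"])
    labels = {nc: merged[f"class{nc}"].to_numpy() for nc in (2, 3, 4)}
    rankings = {}
    for nc in (2, 3, 4):
        r = mrmr_rank(merged[list(FEATURE_NAMES)], labels[nc])
        rankings[nc] = r
        with open(outdir / f"ranking_class{nc}.json", "w") as fh:
            json.dump(r.to_dict(), fh, indent=2)
        _register(manifest, outdir / f"ranking_class{nc}.json")
    manifest.stages.append(("rank", round(time.perf_counter() - t0, 3)))

    t0 = time.perf_counter()
    protocol = _scaled_protocol(len(merged), rounds, eval_seed)
    result = evaluate_grid(
        merged, labels, merged["F_unified"].to_numpy(), rankings, protocol
    )
    result.table.to_csv(outdir / "evaluation_grid.csv", index=False)
    _register(manifest, outdir / "evaluation_grid.csv")
    manifest.stages.append(("evaluate", round(time.perf_counter() - t0, 3)))

    t0 = time.perf_counter()
    meta = {"seed": config.seed, "weights": weights.as_dict()}
    for model_name, rk in (("eye_tracker", rankings[4]), ("blink_detector", None)):
        model = fit_assessment_model(
            model_name,
            merged,
            labels,
            merged["F_unified"].to_numpy(),
            ranking=rk,
            metadata=meta,
        )
        joblib.dump(model, outdir / f"model_{model_name}.joblib")
        _register(manifest, outdir / f"model_{model_name}.joblib")
    manifest.stages.append(("fit_models", round(time.perf_counter() - t0, 3)))

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
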