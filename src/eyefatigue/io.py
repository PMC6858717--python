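"""Plain-text readers/writers for the pipeline's interchange formats.

Gaze CSV: header ``t,x,y,valid``; ``t`` with 6 decimals, ``valid`` in {0,1},
invalid rows carry empty ``x``/``y`` fields.  Optometry, SSQ, feature, and
fatigue tables are ordinary CSV round-tripped through pandas.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from eyefatigue.config import FEATURE_NAMES, INDICATORS
from eyefatigue.errors import ValidationError
from eyefatigue.ssq_scoring import SSQ_ITEMS
from eyefatigue.synthetic_data.gaze import GazeStream


def write_gaze_csv(stream: GazeStream, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "x", "y", "valid"])
        for t, x, y, v in zip(stream.t, stream.x, stream.y, stream.valid):
            if v:
                w.writerow([f"{t:.6f}", f"{x:.3f}", f"{y:.3f}", 1])
            else:
                w.writerow([f"{t:.6f}", "", "", 0])


def read_gaze_csv(path) -> GazeStream:
    t, x, y, valid = [], [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"t", "x", "y", "valid"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: gaze CSV must have header t,x,y,valid")
        for row in reader:
            t.append(float(row["t"]))
            v = row["valid"].strip() == "1"
            valid.append(v)
            x.append(float(row["x"]) if v and row["x"] != "" else np.nan)
            y.append(float(row["y"]) if v and row["y"] != "" else np.nan)
    return GazeStream(t=np.array(t), x=np.array(x), y=np.array(y), valid=np.array(valid))


def gaze_csv_name(subject: int, epoch: int) -> str:
    return f"gaze_s{subject:03d}_e{epoch}.csv"


def write_gaze_dir(gaze: dict, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (subject, epoch), stream in sorted(gaze.items()):
        p = outdir / gaze_csv_name(subject, epoch)
        write_gaze_csv(stream, p)
        paths.append(p)
    return paths


def read_gaze_dir(indir) -> dict:
    gaze = {}
    for p in sorted(Path(indir).glob("gaze_s*_e*.csv")):
        stem = p.stem  # gaze_sNNN_eK
        subject = int(stem.split("_")[1][1:])
        epoch = int(stem.split("_")[2][1:])
        gaze[(subject, epoch)] = read_gaze_csv(p)
    return gaze


def write_optometry_csv(panels: pd.DataFrame, path) -> None:
    cols = ["subject", "epoch", "arm", *INDICATORS]
    panels[cols].to_csv(path, index=False, float_format="%.6f")


def read_optometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "epoch", *INDICATORS) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: optometry CSV missing columns {missing}")
    return df


def write_ssq_csv(responses: pd.DataFrame, path) -> None:
    cols = ["subject", "epoch"] + [f"item_{i}" for i in range(1, len(SSQ_ITEMS) + 1)]
    responses[cols].to_csv(path, index=False)


def read_ssq_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    item_cols = [f"item_{i}" for i in range(1, len(SSQ_ITEMS) + 1)]
    missing = [c for c in ("subject", "epoch", *item_cols) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: SSQ CSV missing columns {missing}")
    return df


def write_features_csv(features: pd.DataFrame, path) -> None:
    cols = ["subject", "epoch", *FEATURE_NAMES]
    features[cols].to_csv(path, index=False, float_format="%.9g")


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "epoch", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: feature CSV missing columns {missing}")
    return df
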