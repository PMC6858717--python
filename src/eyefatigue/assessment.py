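"""SVM-based graded and continuous fatigue assessment.

The evaluation grid trains, for every feature set x kernel, three
classifiers (2/3/4 graded classes) and two regressors (epsilon- and
nu-SVR) on repeated random 320/100 holdout splits with C = 1, reporting
mean test accuracy or mean Pearson correlation over rounds.  The two
deliverable assessment bundles pair a fixed kernel with each task: RBF for
2-class, linear for 3-class, polynomial for 4-class, and a polynomial
epsilon regressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR, NuSVR

from eyefatigue.config import BLINK_FEATURES, FEATURE_NAMES
from eyefatigue.errors import ValidationError
from eyefatigue.mrmr import Ranking, build_feature_sets

logger = logging.getLogger(__name__)

#: Kernel numbering used in result tables (kernel 1..4).
KERNELS = ("linear", "poly", "rbf", "sigmoid")

CLASSIFICATION_TASKS = ("class2", "class3", "class4")
REGRESSION_TASKS = ("eps_reg", "nonlin_reg")

#: Task -> kernel choices for the deliverable assessment bundles.
MODEL_KERNELS = {"class2": "rbf", "class3": "linear", "class4": "poly", "reg": "poly"}


@dataclass
class EvalProtocol:
    """Holdout evaluation protocol (320 train / 100 test, 100 rounds, C=1)."""

    train_n: int = 320
    test_n: int = 100
    rounds: int = 100
    C: float = 1.0
    epsilon: float = 0.1
    nu: float = 0.5
    kernels: tuple = KERNELS
    standardize: bool = True
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.train_n + self.test_n != n_samples:
            raise ValidationError(
                f"train_n + test_n = {self.train_n + self.test_n} != n_samples = {n_samples}"
            )
        if self.rounds < 1:
            raise ValidationError("rounds must be >= 1")


@dataclass
class EvalResult:
    """Mean metric per (feature set, task, kernel) plus per-round values."""

    table: pd.DataFrame
    rounds: dict = field(default_factory=dict)  # (set, task, kernel) -> np.ndarray

    def mean(self, feature_set: str, task: str, kernel: str) -> float:
        m = self.table
        row = m[(m.feature_set == feature_set) & (m.task == task) & (m.kernel == kernel)]
        return float(row["mean_score"].iloc[0])


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _make_estimator(task: str, kernel: str, protocol: EvalProtocol):
    common = dict(kernel=kernel, C=protocol.C, gamma="scale", degree=3, coef0=0.0)
    if task in CLASSIFICATION_TASKS:
        return SVC(**common)
    if task == "eps_reg":
        return SVR(epsilon=protocol.epsilon, **common)
    if task == "nonlin_reg":
        return NuSVR(nu=protocol.nu, **common)
    raise ValidationError(f"unknown task {task!r}")


def _draw_splits(rng, n, protocol, y=None, max_redraws=1000):
    """Per-round test-index draws; classification splits keep all classes in train."""
    splits = []
    for _ in range(protocol.rounds):
        for _ in range(max_redraws):
            test_idx = rng.choice(n, size=protocol.test_n, replace=False)
            if y is None:
                break
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            if len(np.unique(y[mask])) == len(np.unique(y)):
                break
            logger.info("redrawing split: a class was absent from the training fold")
        splits.append(np.sort(test_idx))
    return splits


def evaluate_grid(
    features: pd.DataFrame,
    labels: dict,
    target: np.ndarray,
    rankings: dict,
    protocol: EvalProtocol | None = None,
    feature_sets_override: dict | None = None,
) -> EvalResult:
    """Run the full (feature set x kernel x task) holdout grid.

    ``labels`` maps class counts {2,3,4} to discrete label arrays;
    ``target`` is the continuous unified fatigue; ``rankings`` maps class
    counts to :class:`Ranking` objects (regressions reuse the 4-class
    ranking's sets).
    """
    protocol = protocol or EvalProtocol()
    n = len(features)
    protocol.validate(n)
    X_all = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    target = np.asarray(target, dtype=float)

    def sets_for(nc: int) -> dict:
        if feature_sets_override is not None:
            return feature_sets_override
        return build_feature_sets(rankings[nc])

    task_specs = [(f"class{nc}", labels[nc], sets_for(nc)) for nc in (2, 3, 4)]
    task_specs += [(t, target, sets_for(4)) for t in REGRESSION_TASKS]

    rng = np.random.default_rng(protocol.seed)
    records = []
    per_round = {}
    for task, y, fsets in task_specs:
        y = np.asarray(y)
        is_clf = task in CLASSIFICATION_TASKS
        splits = _draw_splits(rng, n, protocol, y if is_clf else None)
        for set_name, set_features in fsets.items():
            cols = [FEATURE_NAMES.index(f) for f in set_features]
            X = X_all[:, cols]
            for kernel in protocol.kernels:
                scores = np.empty(protocol.rounds)
                for r, test_idx in enumerate(splits):
                    mask = np.ones(n, dtype=bool)
                    mask[test_idx] = False
                    Xtr, Xte = X[mask], X[test_idx]
                    if protocol.standardize:
                        Xtr, Xte = _standardize(Xtr, Xte)
                    est = _make_estimator(task, kernel, protocol)
                    est.fit(Xtr, y[mask])
                    pred = est.predict(Xte)
                    if is_clf:
                        scores[r] = float(np.mean(pred == y[test_idx]))
                    else:
                        scores[r] = _pearson(pred, y[test_idx])
                per_round[(set_name, task, kernel)] = scores
                records.append(
                    {
                        "feature_set": set_name,
                        "task": task,
                        "kernel": kernel,
                        "kernel_number": KERNELS.index(kernel) + 1,
                        "mean_score": scores.mean(),
                        "sd_score": scores.std(ddof=1) if len(scores) > 1 else 0.0,
                    }
                )
    return EvalResult(table=pd.DataFrame(records), rounds=per_round)


@dataclass
class AssessmentModel:
    """A deliverable bundle: three graded classifiers plus one regressor."""

    name: str
    feature_names: list
    classifiers: dict  # n_classes -> fitted SVC
    regressor: SVR
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    def _prepare(self, features) -> np.ndarray:
        if hasattr(features, "as_dict"):
            features = features.as_dict()
        if isinstance(features, (pd.Series, dict)):
            try:
                x = np.array([float(features[f]) for f in self.feature_names])
            except KeyError as exc:
                raise ValidationError(
                    f"{self.name} model requires features {self.feature_names}"
                ) from exc
        else:
            x = np.asarray(features, dtype=float).ravel()
            if len(x) != len(self.feature_names):
                raise ValidationError(
                    f"{self.name} model expects {len(self.feature_names)} features "
                    f"({self.feature_names}), got {len(x)}"
                )
        return (x - self.scaler_mean) / self.scaler_sd


def fit_assessment_model(
    name: str,
    features: pd.DataFrame,
    labels: dict,
    target: np.ndarray,
    ranking: Ranking | None = None,
    *,
    C: float = 1.0,
    epsilon: float = 0.1,
    metadata: dict | None = None,
) -> AssessmentModel:
    """Fit one deliverable bundle on the full sample set.

    ``name`` is ``"eye_tracker"`` (all ten features, ranking-ordered) or
    ``"blink_detector"`` (the four blink features).
    """
    if name == "eye_tracker":
        feat_names = list(ranking.order) if ranking is not None else list(FEATURE_NAMES)
    elif name == "blink_detector":
        feat_names = list(BLINK_FEATURES)
    else:
        raise ValidationError(f"unknown model name {name!r}")
    missing = [f for f in feat_names if f not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing columns for {name}: {missing}")
    X = features[feat_names].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    classifiers = {}
    for nc in (2, 3, 4):
        clf = SVC(kernel=MODEL_KERNELS[f"class{nc}"], C=C, gamma="scale", degree=3, coef0=0.0)
        clf.fit(Xs, np.asarray(labels[nc]))
        classifiers[nc] = clf
    reg = SVR(kernel=MODEL_KERNELS["reg"], C=C, epsilon=epsilon, gamma="scale", degree=3, coef0=0.0)
    reg.fit(Xs, np.asarray(target, dtype=float))
    return AssessmentModel(
        name=name,
        feature_names=feat_names,
        classifiers=classifiers,
        regressor=reg,
        scaler_mean=mu,
        scaler_sd=sd,
        metadata=metadata or {},
    )


def assess(model: AssessmentModel, features, baseline=None) -> dict:
    """Graded (2/3/4-class) and continuous fatigue for one unified window.

    ``baseline`` may carry the subject's epoch-1 raw feature vector; a
    nonzero baseline signals that ``features`` was not unified.
    """
    if baseline is not None:
        b = np.asarray(
            [baseline[f] for f in model.feature_names]
            if isinstance(baseline, (dict, pd.Series))
            else baseline,
            dtype=float,
        )
        if np.any(np.abs(b) > 1e-9):
            raise ValidationError(
                "features appear non-unified: attached epoch-1 baseline is nonzero; "
                "subtract the subject's first-epoch features before assessing"
            )
    x = model._prepare(features)[None, :]
    out = {f"class{nc}": int(clf.predict(x)[0]) for nc, clf in model.classifiers.items()}
    out["continuous"] = float(model.regressor.predict(x)[0])
    return out
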