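"""Least-squares SVM classification with nested LOOCV configuration selection.

Subjects are classified (healthy control vs. mTBI) from their per-state mean
connectivity vectors after nuisance covariates are regressed out.  The
classifier is a linear least-squares SVM — squared-error slacks with equality
constraints, so training reduces to one symmetric linear system — evaluated by
leave-one-out cross-validation (LOOCV) with AUC as the score.  Configuration
selection is doubly cross-validated: an outer LOOCV leaves one subject out,
an inner LOOCV scores every analysis configuration on the remaining subjects,
and the inner winner classifies the held-out subject, yielding an unbiased
final AUC plus a full subjects-by-configurations AUC grid.  Significance of
per-configuration mean AUCs is judged against a label-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .preprocess import PipelineConfig

__all__ = [
    "FeatureSet",
    "LsSvmModel",
    "ClassificationResult",
    "build_features",
    "adjust_features",
    "train_ls_svm",
    "loocv_auc",
    "enumerate_configs",
    "nested_selection",
    "bootstrap_null",
]

ADJUST_COVARIATES = ["gender", "age", "TRN", "ROT", "spk"]


@dataclass
class FeatureSet:
    """Per-subject feature rows (concatenated per-state mean dFNC vectors)
    with binary diagnosis labels (HC=0, mTBI=1)."""

    features: np.ndarray       # (n_subjects, n_features)
    labels: np.ndarray         # (n_subjects,) in {0, 1}
    subject_ids: list[str] = field(default_factory=list)
    config_id: str = ""
    imputed: np.ndarray | None = None   # boolean mask of imputed entries

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("one label per subject required")


def build_features(
    state_means: np.ndarray,
    labels: np.ndarray,
    occupancy_pct: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    config_id: str = "",
) -> FeatureSet:
    """Flatten (subjects, states, edges) mean-connectivity tensors into feature
    rows; a state a subject never visited is imputed to the cohort mean for
    that state/edge and flagged.  Occupancy percentages can optionally be
    appended as extra features."""
    sm = np.asarray(state_means, dtype=float)
    n = sm.shape[0]
    flat = sm.reshape(n, -1)
    imputed = np.isnan(flat)
    if imputed.any():
        col_mean = np.nanmean(flat, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        flat = np.where(imputed, col_mean[None, :], flat)
    if occupancy_pct is not None:
        occ = np.asarray(occupancy_pct, dtype=float)
        flat = np.hstack([flat, occ])
        imputed = np.hstack([imputed, np.zeros_like(occ, dtype=bool)])
    return FeatureSet(
        features=flat, labels=np.asarray(labels, dtype=int),
        subject_ids=subject_ids or [], config_id=config_id, imputed=imputed,
    )


def _adjust_matrix(
    x: np.ndarray, cov: np.ndarray,
    train_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Residualize features on [intercept | covariates]; when ``train_idx`` is
    given the regression is fit on those rows only and applied to all rows
    (the fully nested form used inside cross-validation folds)."""
    design = np.column_stack([np.ones(x.shape[0]), cov])
    fit = slice(None) if train_idx is None else train_idx
    beta, *_ = np.linalg.lstsq(design[fit], x[fit], rcond=None)
    return x - design @ beta


def adjust_features(fs: FeatureSet, covariates: pd.DataFrame) -> FeatureSet:
    """Regress gender, age, TRN, ROT and spk out of every feature (diagnosis is
    never touched)."""
    cov = covariates[ADJUST_COVARIATES].to_numpy(dtype=float)
    adjusted = _adjust_matrix(fs.features, cov)
    return FeatureSet(adjusted, fs.labels, fs.subject_ids, fs.config_id, fs.imputed)


@dataclass
class LsSvmModel:
    """Dual solution of the linear least-squares SVM."""

    x_train: np.ndarray
    y_signed: np.ndarray
    alpha: np.ndarray
    bias: float
    C: float

    @property
    def weights(self) -> np.ndarray:
        return (self.alpha * self.y_signed) @ self.x_train

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.weights + self.bias


def train_ls_svm(x: np.ndarray, y: np.ndarray, C: float = 0.01) -> LsSvmModel:
    """Fit min ||w||^2/2 + C * sum e_i^2 subject to y_i (w.x_i + b) = 1 - e_i.

    The KKT conditions give the symmetric linear system

        [ 0   y^T           ] [ b     ]   [ 0 ]
        [ y   yy^T*K + I/2C ] [ alpha ] = [ 1 ]

    with K the linear Gram matrix; labels enter as y in {-1, +1}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("least-squares SVM needs exactly two classes")
    y_signed = np.where(y == classes.max(), 1.0, -1.0)
    n = x.shape[0]
    k = x @ x.T
    omega = np.outer(y_signed, y_signed) * k + np.eye(n) / (2.0 * C)
    a = np.zeros((n + 1, n + 1))
    a[0, 1:] = y_signed
    a[1:, 0] = y_signed
    a[1:, 1:] = omega
    rhs = np.concatenate([[0.0], np.ones(n)])
    sol = np.linalg.solve(a, rhs)
    return LsSvmModel(x_train=x, y_signed=y_signed, alpha=sol[1:],
                      bias=float(sol[0]), C=C)


@dataclass
class ClassificationResult:
    decisions: np.ndarray
    auc: float
    winners: list[str] = field(default_factory=list)
    selection_counts: dict[str, int] = field(default_factory=dict)
    auc_grid: np.ndarray | None = None
    null_threshold: float | None = None


def _loo_decisions(
    x: np.ndarray, y: np.ndarray, C: float,
    cov: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Held-out decision value per subject of ``subset`` (default: all).

    When covariates are supplied, the nuisance regression is refit inside each
    training fold (no leakage from the held-out subject).  Each held-out value
    is centered at its fold's mean training decision so that decisions pooled
    across folds share one operating point — leaving a class out otherwise
    shifts the bias term toward the over-represented class, which would push
    the pooled AUC below chance on label-free data."""
    idx = np.arange(x.shape[0]) if subset is None else np.asarray(subset)
    decisions = np.empty(idx.size)
    for pos, i in enumerate(idx):
        train = idx[idx != i]
        if cov is not None:
            xa = _adjust_matrix(x, cov, train_idx=train)
        else:
            xa = x
        model = train_ls_svm(xa[train], y[train], C=C)
        held = model.decision(xa[i : i + 1])[0]
        decisions[pos] = held - model.decision(xa[train]).mean()
    return decisions


def loocv_auc(
    fs: FeatureSet, C: float = 0.01,
    covariates: pd.DataFrame | None = None,
) -> ClassificationResult:
    """Leave-one-out cross-validated AUC over held-out decision values."""
    if fs.features.shape[0] < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    cov = (covariates[ADJUST_COVARIATES].to_numpy(dtype=float)
           if covariates is not None else None)
    decisions = _loo_decisions(fs.features, fs.labels, C, cov=cov)
    auc = float(roc_auc_score(fs.labels, decisions))
    return ClassificationResult(decisions=decisions, auc=auc)


def enumerate_configs(
    pipelines=("PA", "PB", "PC", "PD"),
    thresholds=(2.5, 3.0, 4.0),
    orders=(60, 70, 80),
    windows=(15, 30, 45),
) -> list[PipelineConfig]:
    """Full Cartesian product of the analysis factors, in stable order."""
    for name, vals in (("pipelines", pipelines), ("thresholds", thresholds),
                       ("orders", orders), ("windows", windows)):
        if not len(vals):
            raise ValueError(f"empty factor list: {name}")
    return [
        PipelineConfig(pipeline_id=p, spike_threshold_sd=t,
                       model_order=o, window_tr=w)
        for p, t, o, w in product(pipelines, thresholds, orders, windows)
    ]


def nested_selection(
    features_by_config: dict[str, FeatureSet],
    C: float = 0.01,
    covariates: pd.DataFrame | None = None,
) -> ClassificationResult:
    """Doubly cross-validated configuration selection.

    Outer LOOCV leaves one subject out; the inner loop runs an independent
    LOOCV per configuration on the remaining subjects and scores it by AUC.
    The configuration with the highest inner AUC (ties: first in enumeration
    order) is trained on those subjects and classifies the held-out one.  The
    final AUC pools the outer held-out decisions; the full subjects-by-
    configurations AUC grid and per-configuration selection counts are kept.
    """
    names = list(features_by_config)
    sets = list(features_by_config.values())
    y = sets[0].labels
    n = y.size
    if any(s.labels.size != n or not np.array_equal(s.labels, y) for s in sets):
        raise ValueError("all configurations must share the same subjects and labels")
    cov = (covariates[ADJUST_COVARIATES].to_numpy(dtype=float)
           if covariates is not None else None)
    grid = np.zeros((n, len(names)))
    decisions = np.empty(n)
    winners: list[str] = []
    all_idx = np.arange(n)
    for i in range(n):
        rest = all_idx[all_idx != i]
        for c, fs in enumerate(sets):
            try:
                inner = _loo_decisions(fs.features, y, C, cov=cov, subset=rest)
                grid[i, c] = roc_auc_score(y[rest], inner)
            except Exception as exc:  # a failing configuration scores 0
                warnings.warn(f"inner LOOCV failed for {names[c]}: {exc}")
                grid[i, c] = 0.0
        win = int(np.argmax(grid[i]))   # argmax takes the first maximum
        winners.append(names[win])
        fs = sets[win]
        if cov is not None:
            xa = _adjust_matrix(fs.features, cov, train_idx=rest)
        else:
            xa = fs.features
        model = train_ls_svm(xa[rest], y[rest], C=C)
        decisions[i] = (model.decision(xa[i : i + 1])[0]
                        - model.decision(xa[rest]).mean())
    counts = {name: winners.count(name) for name in names}
    auc = float(roc_auc_score(y, decisions))
    return ClassificationResult(decisions=decisions, auc=auc, winners=winners,
                                selection_counts=counts, auc_grid=grid)


def bootstrap_null(
    auc_grid: np.ndarray,
    features_by_config: dict[str, FeatureSet] | None = None,
    B: int = 200,
    seed: int = 0,
    C: float = 0.01,
    method: str = "permutation",
    quantile: float = 0.95,
) -> dict:
    """Null threshold for per-configuration mean AUCs.

    ``method='permutation'`` (the default) rebuilds the null by running a plain
    LOOCV per configuration under ``B`` random label permutations and pooling
    the resulting mean AUCs; ``method='resample'`` instead bootstraps subject
    rows of the observed grid around the chance level.  Configurations whose
    observed mean AUC exceeds the ``quantile`` of the null are flagged.
    """
    if B < 100:
        warnings.warn(f"B={B} permutation replicates is low; threshold will be noisy")
    grid = np.asarray(auc_grid, dtype=float)
    observed = grid.mean(axis=0)
    rng = np.random.default_rng(seed)
    null: list[float] = []
    if method == "permutation":
        if features_by_config is None:
            raise ValueError("permutation null needs the per-configuration features")
        sets = list(features_by_config.values())
        y = sets[0].labels
        for _ in range(B):
            yp = rng.permutation(y)
            for fs in sets:
                dec = _loo_decisions(fs.features, yp, C)
                null.append(float(roc_auc_score(yp, dec)))
    elif method == "resample":
        n = grid.shape[0]
        centered = grid - observed[None, :] + 0.5
        for _ in range(B):
            rows = rng.integers(n, size=n)
            cols = rng.integers(grid.shape[1], size=n)
            null.append(float(centered[rows, cols].mean()))
    else:
        raise ValueError(f"unknown null method {method!r}")
    threshold = float(np.quantile(null, quantile))
    return {
        "null_threshold": threshold,
        "observed_mean_auc": observed,
        "significant": observed > threshold,
        "null_samples": np.asarray(null),
    }
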