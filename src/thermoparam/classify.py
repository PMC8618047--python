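"""Cohort feature assembly, RBF-SVM cross-validation and the position scan.

For a fixed radial offset ``a`` every thermogram contributes one pattern
vector {Tmax, d, q, R, theta}; the cohort's vectors form a feature table
with binary labels (normal = 0, abnormal = 1).  A C-classification SVM
with an RBF kernel is evaluated by stratified K-fold cross-validation
(K = 10 by default), features standardized inside each training fold.
The correct-rate classification CRC is the percentage of out-of-fold
predictions that match the labels.  Scanning CRC over the offset grid
identifies the optimal extraction distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .inverse import DEFAULT_CONSTANTS, ModelConstants, pattern_vector
from .segmentation import RoIProfile

__all__ = [
    "FeatureTable",
    "CVResult",
    "PositionScanResult",
    "CohortError",
    "FEATURE_COLUMNS",
    "build_feature_table",
    "svm_cross_validate",
    "classification_metrics",
    "roc_auc",
    "scan_positions",
    "report",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("Tmax", "d", "q", "R", "theta")

LABEL_CODES = {"normal": 0, "abnormal": 1}


class CohortError(ValueError):
    """Too few usable rows, or a single class, for cross-validation."""


@dataclass
class FeatureTable:
    """Cohort feature matrix (n x 5) with labels at one fixed offset."""

    ids: List[str]
    features: pd.DataFrame
    labels: np.ndarray
    a: float
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if list(self.features.columns) != list(FEATURE_COLUMNS):
            raise ValueError(f"feature columns must be {FEATURE_COLUMNS}")
        if self.features.isna().any().any():
            raise ValueError("feature table must not contain missing values")
        if len(self.features) != len(self.labels) or len(self.ids) != len(self.labels):
            raise ValueError("ids, features and labels must align")


@dataclass
class CVResult:
    """Out-of-fold predictions, decision scores and the CRC percentage."""

    predictions: np.ndarray
    scores: np.ndarray
    crc: float
    n_splits: int
    seed: int


@dataclass
class PositionScanResult:
    """CRC(a) over the offset grid with full metrics per position."""

    a_grid: np.ndarray
    crc: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray
    optimal_a: float
    optimal_index: int
    optimal_labels: np.ndarray
    optimal_predictions: np.ndarray
    optimal_scores: np.ndarray
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    method: str
    seed: int
    n_used: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def build_feature_table(
    profiles: Sequence[RoIProfile],
    labels: Sequence[str],
    method: str,
    a: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    ids: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """One pattern vector per thermogram at offset ``a``.

    Profiles whose extraction fails (off-grid offset, singular inversion,
    fit failure) are dropped and logged rather than imputed.  At least two
    usable rows spanning both classes are required.
    """
    if ids is None:
        ids = [f"t{i:03d}" for i in range(len(profiles))]
    if not (len(profiles) == len(labels) == len(ids)):
        raise ValueError("profiles, labels and ids must align")

    rows, kept_labels, kept_ids = [], [], []
    for pid, prof, lab in zip(ids, profiles, labels):
        if lab not in LABEL_CODES:
            raise ValueError(f"label must be 'normal' or 'abnormal', got {lab!r}")
        try:
            params = pattern_vector(prof, method, a, constants)
        except Exception as exc:  # noqa: BLE001 - any extraction failure drops the row
            logger.warning("dropping %s at a=%g m: %s", pid, a, exc)
            continue
        rows.append(params.as_features())
        kept_labels.append(LABEL_CODES[lab])
        kept_ids.append(pid)

    if len(rows) < 2:
        raise CohortError(f"fewer than 2 usable rows at a={a} m")
    labels_arr = np.asarray(kept_labels, dtype=int)
    if len(np.unique(labels_arr)) < 2:
        raise CohortError(f"single class present at a={a} m")
    features = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_COLUMNS))
    return FeatureTable(ids=kept_ids, features=features, labels=labels_arr, a=a, method=method)


def svm_cross_validate(
    table: FeatureTable,
    C: float = 1.0,
    gamma: "float | str" = "scale",
    n_splits: int = 10,
    seed: int = 0,
    scale_features: bool = True,
) -> CVResult:
    """Stratified K-fold CV of an RBF C-SVM; returns out-of-fold results.

    Features are standardized with statistics of each training fold only
    (disable with ``scale_features=False`` to feed raw features to the
    kernel).  Every row is predicted exactly once, out of fold; CRC is the
    percentage of correct out-of-fold predictions.
    """
    X = table.features.to_numpy(dtype=float)
    y = table.labels
    min_class = int(np.bincount(y).min())
    if min_class < 2:
        raise CohortError("each class needs >= 2 members for stratified CV")
    if n_splits > min_class:
        warnings.warn(
            f"n_splits={n_splits} exceeds the smallest class ({min_class}); reducing"
        )
        n_splits = min_class

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    predictions = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        X_train, X_test = X[train_idx], X[test_idx]
        if scale_features:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        clf = SVC(C=C, kernel="rbf", gamma=gamma)
        clf.fit(X_train, y[train_idx])
        predictions[test_idx] = clf.predict(X_test)
        scores[test_idx] = clf.decision_function(X_test)

    crc = 100.0 * float(np.mean(predictions == y))
    return CVResult(predictions=predictions, scores=scores, crc=crc, n_splits=n_splits, seed=seed)


def classification_metrics(
    predictions: np.ndarray, labels: np.ndarray
) -> Tuple[float, float, float]:
    """Accuracy, sensitivity and specificity in percent (abnormal positive).

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP).
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the labels")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    accuracy = 100.0 * (tp + tn) / len(labels)
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return accuracy, sensitivity, specificity


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC points and trapezoid AUC from continuous decision scores.

    Constant scores carry no ranking information: the degenerate diagonal
    ROC with AUC 0.5 is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the labels")
    if np.ptp(scores) == 0.0:
        warnings.warn("constant decision scores: AUC defaults to 0.5")
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def scan_positions(
    profiles: Sequence[RoIProfile],
    labels: Sequence[str],
    method: str,
    a_grid: Sequence[float],
    constants: ModelConstants = DEFAULT_CONSTANTS,
    C: float = 1.0,
    gamma: "float | str" = "scale",
    n_splits: int = 10,
    seed: int = 0,
    scale_features: bool = True,
    ids: Optional[Sequence[str]] = None,
) -> PositionScanResult:
    """Cross-validated CRC at every positive grid offset; pick the best.

    Offsets where no usable feature table can be built are skipped.  The
    optimal position attains the maximum CRC, ties broken toward the
    smallest offset; full metrics and the ROC curve are reported there.
    """
    usable_a, crcs, accs, sens, specs, aucs, ns = [], [], [], [], [], [], []
    per_a: Dict[float, Tuple[FeatureTable, CVResult]] = {}
    for a in a_grid:
        if a <= 0:
            continue
        try:
            table = build_feature_table(profiles, labels, method, a, constants, ids=ids)
            cv = svm_cross_validate(
                table, C=C, gamma=gamma, n_splits=n_splits, seed=seed,
                scale_features=scale_features,
            )
        except (CohortError, ValueError) as exc:
            logger.warning("skipping a=%g m: %s", a, exc)
            continue
        accuracy, sensitivity, specificity = classification_metrics(cv.predictions, table.labels)
        _, _, auc_value = roc_auc(cv.scores, table.labels)
        usable_a.append(float(a))
        crcs.append(cv.crc)
        accs.append(accuracy)
        sens.append(sensitivity)
        specs.append(specificity)
        aucs.append(auc_value)
        ns.append(len(table.labels))
        per_a[float(a)] = (table, cv)

    if not usable_a:
        raise CohortError("no usable offset in the scan grid")

    crcs_arr = np.asarray(crcs)
    best = int(np.argmax(crcs_arr))  # grid is increasing: first max = smallest a
    optimal_a = usable_a[best]
    best_table, best_cv = per_a[optimal_a]
    fpr, tpr, _ = roc_auc(best_cv.scores, best_table.labels)

    return PositionScanResult(
        a_grid=np.asarray(usable_a),
        crc=crcs_arr,
        accuracy=np.asarray(accs),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(specs),
        auc=np.asarray(aucs),
        optimal_a=optimal_a,
        optimal_index=best,
        optimal_labels=best_table.labels.copy(),
        optimal_predictions=best_cv.predictions.copy(),
        optimal_scores=best_cv.scores.copy(),
        roc_fpr=fpr,
        roc_tpr=tpr,
        method=method,
        seed=seed,
        n_used=np.asarray(ns, dtype=int),
    )


def report(scan: PositionScanResult, out_dir: "str | Path", make_plot: bool = False) -> Dict[str, Path]:
    """Write the scan results as CSV files (created under ``out_dir``).

    crc_by_position.csv: per-offset CRC and metrics; metrics.csv: the
    summary row at the optimal offset; roc.csv: ROC points there.  Output
    is deterministic for a fixed scan.  ``make_plot`` additionally saves a
    CRC-versus-position figure (requires matplotlib).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_pos = pd.DataFrame(
        {
            "a_m": scan.a_grid,
            "crc_pct": scan.crc,
            "accuracy_pct": scan.accuracy,
            "sensitivity_pct": scan.sensitivity,
            "specificity_pct": scan.specificity,
            "auc": scan.auc,
            "n_used": scan.n_used,
        }
    )
    metrics = pd.DataFrame(
        {
            "method": [scan.method],
            "optimal_a_m": [scan.optimal_a],
            "crc_pct": [scan.crc[scan.optimal_index]],
            "accuracy_pct": [scan.accuracy[scan.optimal_index]],
            "sensitivity_pct": [scan.sensitivity[scan.optimal_index]],
            "specificity_pct": [scan.specificity[scan.optimal_index]],
            "auc": [scan.auc[scan.optimal_index]],
            "seed": [scan.seed],
        }
    )
    roc = pd.DataFrame({"fpr": scan.roc_fpr, "tpr": scan.roc_tpr})

    paths = {
        "crc_by_position": out / "crc_by_position.csv",
        "metrics": out / "metrics.csv",
        "roc": out / "roc.csv",
    }
    by_pos.to_csv(paths["crc_by_position"], index=False, float_format="%.10g")
    metrics.to_csv(paths["metrics"], index=False, float_format="%.10g")
    roc.to_csv(paths["roc"], index=False, float_format="%.10g")

    if make_plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(scan.a_grid * 100, scan.crc, marker="o")
        ax.axvline(scan.optimal_a * 100, color="r", ls="--", label=f"optimal a = {scan.optimal_a:.4f} m")
        ax.set_xlabel("radial position a (cm)")
        ax.set_ylabel("CRC (%)")
        ax.legend()
        fig.tight_layout()
        plot_path = out / "crc_by_position.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path

    return paths
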