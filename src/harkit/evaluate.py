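"""Train/test protocols, confusion-matrix reports, and overlap sweeps.

Per-class "accuracy" is the class recall (diagonal over row sum of the
confusion matrix) in percent, and the headline figure is its unweighted
macro mean TRUNCATED (not rounded) to two decimals — the truncation
convention is what reproduces every published mean this package checks
its report arithmetic against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .types import SignalStream, RunConfig


def truncate2(x: float) -> float:
    """Truncate toward zero to two decimals.

    A tiny pre-round (to 9 decimals at the shifted scale) guards
    against binary-float artifacts such as 90.17 being stored as
    90.16999...; without it the floor would drop a whole hundredth.
    """
    return math.trunc(round(x * 100.0, 6)) / 100.0


def macro_mean(per_class_accuracy: np.ndarray | list[float]) -> float:
    """Truncated-to-2-decimals unweighted mean of per-class accuracies (%)"""
    return truncate2(float(np.mean(np.asarray(per_class_accuracy, dtype=float))))


@dataclass
class EvaluationReport:
    """Confusion matrix plus the per-class and macro accuracy summary."""

    confusion: np.ndarray  # K x K, rows = true class
    class_labels: list[str]
    per_class_accuracy: np.ndarray  # percent
    macro: float  # percent, truncated to 2 decimals
    classifier: str = "proposed"
    overlap_ratio: float | None = None

    def to_text(self) -> str:
        lines = [f"Classifier: {self.classifier}"]
        if self.overlap_ratio is not None:
            lines.append(f"Overlap ratio: {self.overlap_ratio:.2f}")
        width = max(len(c) for c in self.class_labels + ["Mean Recognition Accuracy"]) + 2
        lines.append(f"{'Activity':<{width}}Accuracy (%)")
        for label, acc in zip(self.class_labels, self.per_class_accuracy):
            lines.append(f"{label:<{width}}{acc:.2f}")
        lines.append(f"{'Mean Recognition Accuracy':<{width}}{self.macro:.2f}")
        return "\n".join(lines)


def report_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_labels: list[str] | None = None,
    classifier: str = "proposed",
    overlap_ratio: float | None = None,
) -> EvaluationReport:
    """Build the report from true/predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    labels = class_labels if class_labels is not None else sorted(set(y_true))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        missing = [l for l, s in zip(labels, row_sums) if s == 0]
        raise ValueError(f"classes {missing} have no test samples")
    per_class = 100.0 * np.diag(cm) / row_sums
    return EvaluationReport(
        confusion=cm,
        class_labels=[str(l) for l in labels],
        per_class_accuracy=per_class,
        macro=macro_mean(per_class),
        classifier=classifier,
        overlap_ratio=overlap_ratio,
    )


def report_from_accuracies(
    per_class_accuracy: list[float],
    class_labels: list[str] | None = None,
    classifier: str = "proposed",
) -> EvaluationReport:
    """Report built directly from stated per-class accuracies (no
    confusion counts available) — used to check report arithmetic
    against published tables."""
    acc = np.asarray(per_class_accuracy, dtype=float)
    labels = class_labels or [f"C{i + 1}" for i in range(len(acc))]
    return EvaluationReport(
        confusion=np.zeros((len(acc), len(acc)), dtype=int),
        class_labels=labels,
        per_class_accuracy=acc,
        macro=macro_mean(acc),
        classifier=classifier,
    )


def split_frames(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.7,
    seed: int = 0,
    subjects: np.ndarray | None = None,
    protocol: str = "stratified_windows",
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test row indices under either protocol.

    ``stratified_windows`` holds out (1 - fraction) of the frames per
    class; ``leave_subjects_out`` holds out whole subjects (requires
    ``subjects``).
    """
    y = np.asarray(y)
    idx = np.arange(len(y))
    if protocol == "stratified_windows":
        tr, te = train_test_split(
            idx, train_size=fraction, stratify=y, random_state=seed % (2**31)
        )
        return np.sort(tr), np.sort(te)
    if protocol == "leave_subjects_out":
        if subjects is None:
            raise ValueError("leave_subjects_out requires per-frame subject ids")
        subjects = np.asarray(subjects)
        uniq = np.array(sorted(set(subjects)))
        n_test = max(1, int(round((1.0 - fraction) * len(uniq))))
        rng = np.random.default_rng(seed)
        held_out = set(rng.choice(uniq, size=n_test, replace=False))
        te_mask = np.isin(subjects, list(held_out))
        return idx[~te_mask], idx[te_mask]
    raise ValueError(f"unknown split protocol {protocol!r}")


def weight_report(
    histories: list[np.ndarray], feature_names: list[str]
) -> dict[str, list[float]]:
    """Per-trial feature-weight table: rows = feature names, columns =
    trials, cells = best-chromosome gene values."""
    if not histories:
        raise ValueError("no completed trials")
    table: dict[str, list[float]] = {name: [] for name in feature_names}
    for weights in histories:
        if len(weights) != len(feature_names):
            raise ValueError("weight vector length does not match feature registry")
        for name, w in zip(feature_names, weights):
            table[name].append(float(w))
    return table


def sweep_overlaps(
    streams: list[SignalStream],
    ratios: list[float] | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict[float, dict[str, EvaluationReport]]:
    """Re-run the full pipeline at each overlap ratio with the same seed;
    returns {ratio: {classifier_tag: report}}."""
    from .pipeline import run_experiment
    import copy

    ratios = ratios if ratios is not None else [0.10, 0.30, 0.60]
    config = config or RunConfig()
    out: dict[float, dict[str, EvaluationReport]] = {}
    for r in ratios:
        cfg = copy.deepcopy(config)
        cfg.overlap_ratio = r
        result = run_experiment(streams, cfg, seed=seed)
        out[r] = result.reports
    return out
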