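"""End-to-end experiment driver: streams -> frames -> features -> GA ->
templates -> evaluation reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SignalStream, RunConfig
from .preprocess import preprocess_stream, frame
from .features import extract_all, feature_registry
from .ga import GAFeatureSelector
from .classify import TemplateMatchingClassifier, TrainedModel, train_baseline
from .evaluate import report_from_predictions, split_frames, EvaluationReport


@dataclass
class ExperimentResult:
    reports: dict[str, EvaluationReport]
    selector: GAFeatureSelector
    classifier: TemplateMatchingClassifier
    model: TrainedModel
    feature_names: list[str] = field(default_factory=list)


def streams_to_feature_arrays(
    streams: list[SignalStream], config: RunConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Preprocess, frame, and featurize labeled streams.

    Returns (X, y, subjects, feature_names). Each stream is normalized
    with its own extremes (the per-stream convention); frames then
    inherit the stream label and subject.
    """
    X_rows, y_rows, subj_rows = [], [], []
    for s in streams:
        clean = preprocess_stream(
            s, ma_width=config.ma_width, causal=config.causal_smoothing
        )
        for fr in frame(clean, config.window_seconds, config.overlap_ratio):
            fv = extract_all(fr, config)
            X_rows.append(fv.values)
            y_rows.append(fv.label if fv.label is not None else "")
            subj_rows.append(fr.subject_id)
    if not X_rows:
        raise ValueError("no frames produced; streams shorter than one window?")
    names, _ = feature_registry()
    return np.vstack(X_rows), np.array(y_rows), np.array(subj_rows), names


def fit_feature_extremes(X: np.ndarray) -> list[tuple[float, float]]:
    """Per-feature (min, max) over the training table — the extremes used
    to normalize features before selection and matching."""
    return [(float(lo), float(hi)) for lo, hi in zip(X.min(axis=0), X.max(axis=0))]


def apply_feature_extremes(
    X: np.ndarray, extremes: list[tuple[float, float]]
) -> np.ndarray:
    """Min-max map each feature column to [0, 1] under stored training
    extremes, clamping out-of-range values; constant columns map to 0."""
    lo = np.array([e[0] for e in extremes])
    hi = np.array([e[1] for e in extremes])
    span = np.where(hi > lo, hi - lo, 1.0)
    out = np.clip((X - lo) / span, 0.0, 1.0)
    out[:, hi == lo] = 0.0
    return out


def run_experiment(
    streams: list[SignalStream],
    config: RunConfig | None = None,
    seed: int = 0,
    protocol: str = "stratified_windows",
) -> ExperimentResult:
    """Full protocol: split frames, min-max normalize features with the
    training extremes, evolve GA weights on the training partition,
    build class templates, and score the proposed classifier alongside
    the LSVM and random-forest baselines on the test partition
    (baselines see the normalized but unweighted feature table)."""
    config = config or RunConfig()
    X, y, subjects, names = streams_to_feature_arrays(streams, config)
    tr, te = split_frames(
        X, y, fraction=config.split_fraction, seed=seed,
        subjects=subjects, protocol=protocol,
    )
    extremes = fit_feature_extremes(X[tr])
    X = apply_feature_extremes(X, extremes)

    selector = GAFeatureSelector(
        population_size=config.ga.population_size,
        max_generations=config.ga.max_generations,
        crossover_prob=config.ga.crossover_prob,
        mutation_rate=config.ga.mutation_rate,
        tournament_size=config.ga.tournament_size,
        elitism=config.ga.elitism,
        patience=config.ga.patience,
        rf_estimators=config.ga.rf_estimators,
        svm_c=config.ga.svm_c,
        random_state=seed,
    )
    selector.fit(X[tr], y[tr])
    Xw_tr = selector.transform(X[tr])
    Xw_te = selector.transform(X[te])

    clf = TemplateMatchingClassifier(metric=config.similarity)
    clf.fit(Xw_tr, y[tr])
    y_pred = clf.predict(Xw_te)

    class_order = sorted(set(y))
    reports = {
        "proposed": report_from_predictions(
            y[te], y_pred, class_order, "proposed", config.overlap_ratio
        )
    }
    for kind in ("lsvm", "rf"):
        base = train_baseline(kind, X[tr], y[tr], seed=seed)
        reports[kind] = report_from_predictions(
            y[te], base.predict(X[te]), class_order, kind, config.overlap_ratio
        )

    retained = [n for n, keep in zip(names, selector.support_) if keep]
    model = clf.to_model(
        feature_names=retained,
        weights=selector.best_chromosome_,
        extremes=extremes,
        config=config.to_dict(),
    )
    return ExperimentResult(
        reports=reports,
        selector=selector,
        classifier=clf,
        model=model,
        feature_names=names,
    )
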