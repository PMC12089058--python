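"""Evaluation: macro metrics, frozen-pipeline training, online replay,
participant-level leave-one-out cross-validation and source-subset analyses.

All scores are macro-averaged over the two task classes
(Visualization = 0, Workload = 1):

    P_i = TP_i / (TP_i + FP_i)        R_i = TP_i / (TP_i + FN_i)
    F1_i = 2 P_i R_i / (P_i + R_i)    macro = (1/K) Σ_i (·)

with the 0/0 convention that a metric with zero denominator is 0.

Cross-participant evaluation is leakage-proof by construction: in every
fold the held-out participant's samples are absent from every fitting call
(RLS coefficients, scaler, feature selection, hyperparameter search and the
final model all see the training cohort only), and a structural guard
raises if a test-participant window ever reaches a fitting step.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd

from . import classify, featurize, hemo, shortchannel
from .synth import (
    LATERAL,
    MEDIAL,
    SHORT_LATERAL,
    SHORT_MEDIAL,
    MODE_DELTA_HB,
    SessionRecording,
    split_by_groups,
)

SUBSET_ALL = "ALL"
SUBSET_LATERAL = "LATERAL"
SUBSET_MEDIAL = "MEDIAL"
SUBSETS = (SUBSET_ALL, SUBSET_LATERAL, SUBSET_MEDIAL)

POOLED = "POOLED"
PER_FOLD_MEAN = "PER_FOLD_MEAN"

CLASS_NAMES = ("Visualization", "Workload")


class LeakageError(RuntimeError):
    """A held-out participant's data reached a fitting step."""


# ---------------------------------------------------------------------------
# Confusion matrix and macro metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class and macro precision/recall/F1 from a confusion matrix."""

    confusion: np.ndarray  # [K, K], rows true, columns predicted
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int
    class_names: tuple[str, ...] = CLASS_NAMES

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": name,
                "precision": round_half_up(p),
                "recall": round_half_up(r),
                "f1": round_half_up(f),
            }
            for name, p, r, f in zip(self.class_names, self.precision, self.recall, self.f1)
        ]
        rows.append(
            {
                "class": "Macro average",
                "precision": round_half_up(self.macro_precision),
                "recall": round_half_up(self.macro_recall),
                "f1": round_half_up(self.macro_f1),
            }
        )
        return pd.DataFrame(rows)


def round_half_up(x: float, digits: int = 3) -> float:
    """Half-up rounding for report display (0.9635 -> 0.964)."""
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, classes: tuple = classify.CLASS_LABELS
) -> np.ndarray:
    """K x K (true, predicted) count table in the fixed class order."""
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    cm = np.asarray(cm)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp  # predicted-as-i but not i
    fn = cm.sum(axis=1) - tp  # truly i but predicted otherwise
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return MetricsReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        n=int(cm.sum()),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    return metrics_from_confusion(confusion_from_labels(y_true, y_pred))


def aggregate_participants(macro_f1s: list[float]) -> tuple[float, float]:
    """(mean, population sd) of per-participant macro F1 scores."""
    if len(macro_f1s) == 0:
        raise ValueError("empty participant list")
    arr = np.asarray(macro_f1s, float)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# Source subsets
# ---------------------------------------------------------------------------

_SUBSET_SIDES = {
    SUBSET_ALL: None,
    SUBSET_LATERAL: {LATERAL, SHORT_LATERAL},
    SUBSET_MEDIAL: {MEDIAL, SHORT_MEDIAL},
}


def source_subset(rec: SessionRecording, subset: str) -> SessionRecording:
    """Retain long channels of one probe side plus its short channel."""
    if subset not in _SUBSET_SIDES:
        raise ValueError(f"unknown source subset {subset!r}")
    sides = _SUBSET_SIDES[subset]
    if sides is None:
        return rec.copy()
    idx = [i for i, c in enumerate(rec.channels) if c.side in sides]
    return rec.select_channels(idx)


# ---------------------------------------------------------------------------
# Frozen pipeline: train once, apply without updating
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of one preprocessing + classification pipeline."""

    window: featurize.WindowSpec = field(default_factory=featurize.WindowSpec)
    statistics: tuple[str, ...] = featurize.ONLINE_STATISTICS
    k_best: int | None = featurize.DEFAULT_K_BEST
    model_family: str = classify.SVM_LINEAR
    model_params: dict = field(default_factory=lambda: {"C": 1.0})
    subset: str = SUBSET_ALL
    rls_forgetting: float = shortchannel.DEFAULT_FORGETTING
    rls_delta: float = shortchannel.DEFAULT_DELTA
    causal_bandpass: bool = True
    seed: int = 0


@dataclass
class TrainedPipeline:
    """Frozen preprocessing state plus a fitted classifier — the unit shipped
    from training to online replay."""

    config: PipelineConfig
    rls_state: shortchannel.RlsState
    scaler: featurize.ScalerParams
    selector: featurize.SelectorParams | None
    model: classify.FittedModel
    feature_names: list[str]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedPipeline":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError("file does not contain a TrainedPipeline")
        return obj


def _preprocess(rec: SessionRecording, cfg: PipelineConfig) -> SessionRecording:
    """Subset channels and bandpass (the stateless stages)."""
    if rec.mode != MODE_DELTA_HB:
        raise ValueError("pipeline expects DELTA_HB recordings; run hemo.convert_recording first")
    sub = source_subset(rec, cfg.subset)
    spec = hemo.BandpassSpec(fs_hz=sub.fs_hz, causal=cfg.causal_bandpass)
    return hemo.bandpass_recording(sub, spec)


def train_pipeline(
    train_recs: list[SessionRecording] | SessionRecording, cfg: PipelineConfig
) -> TrainedPipeline:
    """Fit RLS -> features -> scaler -> (optional) F-test selector -> model,
    in order, on training data only; returns the frozen bundle."""
    if isinstance(train_recs, SessionRecording):
        train_recs = [train_recs]
    pre = [_preprocess(r, cfg) for r in train_recs]
    rls_state = shortchannel.fit_concatenated(pre, cfg.rls_forgetting, cfg.rls_delta)
    denoised = [shortchannel.apply_recording(r, rls_state) for r in pre]
    table = featurize.FeatureTable.concatenate(
        [featurize.build_feature_table(r, cfg.window, cfg.statistics) for r in denoised]
    )
    if len(np.unique(table.y)) < 2:
        raise ValueError("training data must contain both task classes")
    scaler = featurize.fit_scaler(table.X)
    X = featurize.apply_scaler(table.X, scaler)
    selector = None
    if cfg.k_best is not None:
        selector = featurize.select_k_best(X, table.y, cfg.k_best)
        X = featurize.apply_selector(X, selector)
    model = classify.fit(cfg.model_family, X, table.y, cfg.model_params, cfg.seed)
    return TrainedPipeline(
        config=cfg,
        rls_state=rls_state,
        scaler=scaler,
        selector=selector,
        model=model,
        feature_names=table.names,
    )


def pipeline_features(pipeline: TrainedPipeline, rec: SessionRecording) -> featurize.FeatureTable:
    """Apply the frozen preprocessing (no fitting) and window a recording."""
    pre = _preprocess(rec, pipeline.config)
    den = shortchannel.apply_recording(pre, pipeline.rls_state)
    return featurize.build_feature_table(den, pipeline.config.window, pipeline.config.statistics)


def pipeline_predict(pipeline: TrainedPipeline, table: featurize.FeatureTable) -> np.ndarray:
    X = featurize.apply_scaler(table.X, pipeline.scaler)
    if pipeline.selector is not None:
        X = featurize.apply_selector(X, pipeline.selector)
    return classify.predict(pipeline.model, X)


def online_replay(
    pipeline: TrainedPipeline, test_rec: SessionRecording
) -> tuple[np.ndarray, np.ndarray, MetricsReport]:
    """Replay the real-time experiment on a held-out session.

    Walks each task block in contiguous windows of the pipeline's stride,
    applies the frozen RLS/scaler/selector/model per window, never updates
    any state, and returns (predictions, true labels, metrics).  Emits
    floor(block_samples / stride) predictions per task block.
    """
    table = pipeline_features(pipeline, test_rec)
    preds = pipeline_predict(pipeline, table)
    return preds, table.y, metrics_from_labels(table.y, preds)


def run_online_session(
    session: SessionRecording, cfg: PipelineConfig
) -> tuple[TrainedPipeline, MetricsReport]:
    """Per-participant real-time protocol: train on the first two task groups,
    replay the frozen pipeline on the third."""
    train = split_by_groups(session, (0, 1))
    test = split_by_groups(session, (2,))
    pipeline = train_pipeline([train], cfg)
    _, _, report = online_replay(pipeline, test)
    return pipeline, report


# ---------------------------------------------------------------------------
# Participant-level leave-one-out cross-validation
# ---------------------------------------------------------------------------

def ensure_no_leakage(train_table: featurize.FeatureTable, test_participant: str) -> None:
    """Hard structural guard: the held-out participant's windows must be
    physically absent from every fitting call."""
    if np.any(train_table.participants == test_participant):
        raise LeakageError(
            f"participant {test_participant!r} present in a training table"
        )


@dataclass
class FoldResult:
    test_participant: str
    report: MetricsReport
    chosen_params: dict
    inner_scores: dict


@dataclass
class CellResult:
    """One (family, window, subset) cell: pooled and per-fold metrics."""

    family: str
    window_frames: int
    subset: str
    folds: list[FoldResult]

    @property
    def pooled(self) -> MetricsReport:
        cm = sum(f.report.confusion for f in self.folds)
        return metrics_from_confusion(cm)

    @property
    def per_fold_macro_f1(self) -> list[float]:
        return [f.report.macro_f1 for f in self.folds]

    def macro_f1(self, aggregation: str = POOLED) -> float:
        if aggregation == POOLED:
            return self.pooled.macro_f1
        if aggregation == PER_FOLD_MEAN:
            return float(np.mean(self.per_fold_macro_f1))
        raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass
class CvResult:
    """All (family x window x subset) cells of a LOO-CV sweep."""

    cells: dict[tuple[str, int, str], CellResult]
    participants: list[str]

    def cell(self, family: str, window_frames: int, subset: str = SUBSET_ALL) -> CellResult:
        key = (family, window_frames, subset)
        if key not in self.cells:
            raise KeyError(f"no LOO-CV cell for {key}")
        return self.cells[key]

    def to_frame(self, aggregation: str = POOLED) -> pd.DataFrame:
        rows = []
        for (family, w, subset), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "family": family,
                    "window_frames": w,
                    "subset": subset,
                    "macro_f1": round_half_up(cell.macro_f1(aggregation)),
                    "f1_visualization": round_half_up(cell.pooled.f1[0]),
                    "f1_workload": round_half_up(cell.pooled.f1[1]),
                    "n_windows": cell.pooled.n,
                }
            )
        return pd.DataFrame(rows)


def _inner_cv_select(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    participants: np.ndarray,
    seed: int,
) -> tuple[dict, dict]:
    """Grouped inner LOO over training participants; best mean macro F1 wins,
    ties going to the smallest (earliest-listed) hyperparameter value."""
    candidates = classify.grid_iter(family)
    if len(candidates) == 1:
        return candidates[0], {}
    inner_parts = np.unique(participants)
    scores: dict[str, float] = {}
    for params in candidates:
        fold_scores = []
        for part in inner_parts:
            val = participants == part
            if len(np.unique(y[~val])) < 2 or not np.any(val):
                continue
            model = classify.fit(family, X[~val], y[~val], params, seed)
            preds = classify.predict(model, X[val])
            fold_scores.append(metrics_from_labels(y[val], preds).macro_f1)
        scores[repr(params)] = float(np.mean(fold_scores)) if fold_scores else 0.0
    best = max(candidates, key=lambda p: scores[repr(p)])  # first max: smallest value
    return best, scores


def loocv(
    sessions: list[SessionRecording],
    families: tuple[str, ...] = classify.FAMILIES,
    window_frames: tuple[int, ...] = (100,),
    subsets: tuple[str, ...] = (SUBSET_ALL,),
    statistics: tuple[str, ...] = featurize.ALL_STATISTICS,
    k_best: int | None = None,
    rls_forgetting: float = shortchannel.DEFAULT_FORGETTING,
    rls_delta: float = shortchannel.DEFAULT_DELTA,
    seed: int = 0,
) -> CvResult:
    """Participant-level LOO-CV over model families, window sizes and source
    subsets.

    Per fold, the preprocessing pipeline (RLS coefficients, scaler, optional
    F-test selector) is fitted on the training cohort only and applied frozen
    to the held-out participant; hyperparameters are chosen by grouped inner
    LOO over the training participants.  Offline analyses use the extended
    statistic set, zero-phase bandpass and no K-best selection by default.
    """
    participants = [s.participant_id for s in sessions]
    if len(set(participants)) != len(participants):
        raise ValueError("participant ids must be unique")
    if len(participants) < 3:
        raise ValueError("LOO-CV requires at least 3 participants")

    cells: dict[tuple[str, int, str], CellResult] = {}
    for subset in subsets:
        # stateless stages once per subset
        pre = []
        for s in sessions:
            sub = source_subset(s, subset)
            pre.append(hemo.bandpass_recording(sub, hemo.BandpassSpec(fs_hz=sub.fs_hz)))
        # RLS is window-independent: fit per fold on the training cohort,
        # apply frozen to every session of that fold
        fold_denoised: list[list[SessionRecording]] = []
        for ti in range(len(participants)):
            train_recs = [r for i, r in enumerate(pre) if i != ti]
            rls = shortchannel.fit_concatenated(train_recs, rls_forgetting, rls_delta)
            fold_denoised.append([shortchannel.apply_recording(r, rls) for r in pre])
        for w in window_frames:
            spec = featurize.WindowSpec(window_frames=w, fs_hz=sessions[0].fs_hz)
            fold_data = []  # (test participant, train table scaled, test table scaled)
            for ti, test_part in enumerate(participants):
                tables = [
                    featurize.build_feature_table(r, spec, statistics)
                    for r in fold_denoised[ti]
                ]
                train_tab = featurize.FeatureTable.concatenate(
                    [t for i, t in enumerate(tables) if i != ti]
                )
                test_tab = tables[ti]
                ensure_no_leakage(train_tab, test_part)
                scaler = featurize.fit_scaler(train_tab.X)
                Xtr = featurize.apply_scaler(train_tab.X, scaler)
                Xte = featurize.apply_scaler(test_tab.X, scaler)
                if k_best is not None:
                    sel = featurize.select_k_best(Xtr, train_tab.y, k_best)
                    Xtr = featurize.apply_selector(Xtr, sel)
                    Xte = featurize.apply_selector(Xte, sel)
                fold_data.append(
                    (test_part, Xtr, train_tab.y, train_tab.participants, Xte, test_tab.y)
                )
            for family in families:
                folds = []
                for test_part, Xtr, ytr, ptr, Xte, yte in fold_data:
                    if np.any(ptr == test_part):
                        raise LeakageError(
                            f"participant {test_part!r} in both train and test"
                        )
                    params, inner = _inner_cv_select(family, Xtr, ytr, ptr, seed)
                    model = classify.fit(family, Xtr, ytr, params, seed)
                    preds = classify.predict(model, Xte)
                    folds.append(
                        FoldResult(
                            test_participant=test_part,
                            report=metrics_from_labels(yte, preds),
                            chosen_params=params,
                            inner_scores=inner,
                        )
                    )
                cells[(family, w, subset)] = CellResult(family, w, subset, folds)
    return CvResult(cells=cells, participants=participants)


def window_row_mean(macro_f1s: list[float]) -> float:
    """Across-window mean of one family's macro F1 row (the sweep table's
    Mean column), displayed half-up at 3 decimals."""
    if len(macro_f1s) == 0:
        raise ValueError("empty row")
    return round_half_up(float(np.mean(macro_f1s)))


def summarize_window_sweep(
    cv: CvResult,
    families: tuple[str, ...] | None = None,
    window_frames: tuple[int, ...] | None = None,
    subset: str = SUBSET_ALL,
    aggregation: str = POOLED,
) -> pd.DataFrame:
    """Family x window macro-F1 table with an across-window Mean column.

    A missing (family, window) cell raises rather than propagating NaN.
    """
    if families is None:
        families = tuple(sorted({f for (f, _, s) in cv.cells if s == subset}))
    if window_frames is None:
        window_frames = tuple(sorted({w for (_, w, s) in cv.cells if s == subset}))
    rows = {}
    for family in families:
        vals = [cv.cell(family, w, subset).macro_f1(aggregation) for w in window_frames]
        rows[family] = [round_half_up(v) for v in vals] + [
            round_half_up(float(np.mean(vals)))
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[str(w) for w in window_frames] + ["Mean"]
    )
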