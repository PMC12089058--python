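"""Windowed feature extraction for denoised hemodynamic channels.

Task blocks are cut into consecutive non-overlapping windows of a fixed
frame count (100 frames ≈ 17.24 s at 5.8 Hz; the offline sweep uses 50-300).
Each window yields per-channel statistics — max and mean for the real-time
pipeline, plus standard deviation, skewness and regression slope for the
offline analyses — which are standardised with training-set parameters and,
for the real-time pipeline, reduced to the K=10 features with the largest
one-way ANOVA F statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.feature_selection import f_classif

from .synth import CHROMOPHORES, LONG_SIDES, REST, SessionRecording

ONLINE_STATISTICS = ("max", "mean")
ALL_STATISTICS = ("max", "mean", "std", "skew", "slope")
WINDOW_SWEEP_FRAMES = (50, 100, 150, 200, 250, 300)
DEFAULT_K_BEST = 10


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length segmentation: ``window_frames`` per window, stride
    defaulting to the window length (non-overlapping)."""

    window_frames: int = 100
    stride: int | None = None
    fs_hz: float = 5.8

    def __post_init__(self) -> None:
        if self.window_frames <= 0:
            raise ValueError("window_frames must be positive")
        if self.stride is not None and self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else self.window_frames

    @property
    def duration_s(self) -> float:
        return self.window_frames / self.fs_hz


@dataclass
class LabeledWindow:
    data: np.ndarray  # [window_frames, n_channels]
    label: str
    group: int
    participant_id: str
    start: int  # sample index of the window start in the recording


def long_channel_indices(rec: SessionRecording) -> list[int]:
    """Long ΔHb channels in (position, HbO-before-HbR) order; shorts excluded
    from featurization (they exist only as regressors)."""
    idx = [
        i
        for i, c in enumerate(rec.channels)
        if c.side in LONG_SIDES and c.kind in CHROMOPHORES
    ]
    return sorted(idx, key=lambda i: (rec.channels[i].position, rec.channels[i].kind != "HbO"))


def segment(
    rec: SessionRecording, spec: WindowSpec, include_rest: bool = False
) -> list[LabeledWindow]:
    """Cut each task block into consecutive windows of exactly W frames.

    Windows never straddle block boundaries (so no window mixes tasks);
    partial trailing windows are dropped.
    """
    W, stride = spec.window_frames, spec.effective_stride
    chan_idx = long_channel_indices(rec)
    # contiguous runs of constant (label, group)
    keys = [f"{l}|{g}" for l, g in zip(rec.labels, rec.groups)]
    change = np.flatnonzero(
        np.concatenate(([True], np.array(keys[1:]) != np.array(keys[:-1]), [True]))
    )
    windows: list[LabeledWindow] = []
    any_block_fits = False
    for a, b in zip(change[:-1], change[1:]):
        label = str(rec.labels[a])
        if label == REST and not include_rest:
            continue
        if b - a >= W:
            any_block_fits = True
        for start in range(a, b - W + 1, stride):
            windows.append(
                LabeledWindow(
                    data=rec.data[np.ix_(range(start, start + W), chan_idx)],
                    label=label,
                    group=int(rec.groups[a]),
                    participant_id=rec.participant_id,
                    start=int(start),
                )
            )
    if not any_block_fits:
        raise ValueError(f"window of {W} frames longer than every task block")
    return windows


# ---------------------------------------------------------------------------
# Per-window statistics
# ---------------------------------------------------------------------------

def _slope_per_second(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """OLS slope of each column against time in seconds (fs-invariant units)."""
    t = np.arange(x.shape[0]) / fs_hz
    tc = t - t.mean()
    denom = np.sum(tc**2)
    return (tc @ (x - x.mean(axis=0))) / denom


def extract_features(
    window: np.ndarray, statistics: tuple[str, ...] = ONLINE_STATISTICS, fs_hz: float = 5.8
) -> np.ndarray:
    """Per-channel statistics of one [frames, channels] window, concatenated
    channel-major (channel 0 stats, channel 1 stats, ...).

    Skewness is the Fisher definition without bias correction, defined as 0
    for zero-variance windows; std is the unbiased (ddof=1) sample sd.
    """
    x = np.atleast_2d(np.asarray(window, float))
    if x.shape[0] == 0:
        raise ValueError("empty window")
    unknown = set(statistics) - set(ALL_STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    parts = {}
    if "max" in statistics:
        parts["max"] = x.max(axis=0)
    if "mean" in statistics:
        parts["mean"] = x.mean(axis=0)
    if "std" in statistics:
        parts["std"] = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    if "skew" in statistics:
        # zero-variance windows are a defined degenerate case (skew = 0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sk = sps.skew(x, axis=0, bias=True)
        parts["skew"] = np.nan_to_num(sk, nan=0.0)
    if "slope" in statistics:
        parts["slope"] = (
            _slope_per_second(x, fs_hz) if x.shape[0] > 1 else np.zeros(x.shape[1])
        )
    stacked = np.column_stack([parts[s] for s in statistics])  # [channels, stats]
    return stacked.ravel()


def feature_names(
    rec: SessionRecording, statistics: tuple[str, ...] = ONLINE_STATISTICS
) -> list[str]:
    idx = long_channel_indices(rec)
    return [f"{rec.channels[i].name}_{s}" for i in idx for s in statistics]


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Windows x features matrix with task labels, participant ids and
    protocol group indices."""

    X: np.ndarray
    y: np.ndarray  # task label per window ("A"/"B")
    participants: np.ndarray
    groups: np.ndarray
    names: list[str]

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.X[mask], self.y[mask], self.participants[mask], self.groups[mask], self.names
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df["label"] = self.y
        df["participant"] = self.participants
        df["group"] = self.groups
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def concatenate(cls, tables: list["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        names = tables[0].names
        if any(t.names != names for t in tables):
            raise ValueError("feature name mismatch")
        return cls(
            np.vstack([t.X for t in tables]),
            np.concatenate([t.y for t in tables]),
            np.concatenate([t.participants for t in tables]),
            np.concatenate([t.groups for t in tables]),
            names,
        )


def build_feature_table(
    rec: SessionRecording,
    spec: WindowSpec,
    statistics: tuple[str, ...] = ONLINE_STATISTICS,
) -> FeatureTable:
    """Segment a denoised recording and extract per-window features."""
    wins = segment(rec, spec)
    X = np.vstack([extract_features(w.data, statistics, rec.fs_hz) for w in wins])
    return FeatureTable(
        X=X,
        y=np.array([w.label for w in wins]),
        participants=np.array([w.participant_id for w in wins]),
        groups=np.array([w.group for w in wins]),
        names=feature_names(rec, statistics),
    )


# ---------------------------------------------------------------------------
# Scaling (training-set parameters, frozen for test data)
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature mean/sd learned on training rows.  Constant features are
    flagged and passed through centred (divisor 1).  Note that applying
    frozen parameters twice is not idempotent — the second application
    rescales again."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # bool flag per feature

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "constant": self.constant.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            np.asarray(d["mean"], float),
            np.asarray(d["sd"], float),
            np.asarray(d["constant"], bool),
        )


def fit_scaler(X_train: np.ndarray) -> ScalerParams:
    X = np.asarray(X_train, float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0.0
    sd = np.where(constant, 1.0, sd)
    return ScalerParams(mean=mean, sd=sd, constant=constant)


def apply_scaler(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    return (np.asarray(X, float) - params.mean) / params.sd


# ---------------------------------------------------------------------------
# F-test feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectorParams:
    """Indices of the K features with the largest one-way ANOVA F statistic
    on the training rows; ties broken toward the lower feature index."""

    k: int
    selected: np.ndarray  # sorted feature indices
    f_statistic: np.ndarray  # per-feature F

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "selected": self.selected.tolist(),
            "f_statistic": self.f_statistic.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectorParams":
        return cls(int(d["k"]), np.asarray(d["selected"], int), np.asarray(d["f_statistic"], float))


def select_k_best(X_train: np.ndarray, y_train: np.ndarray, k: int = DEFAULT_K_BEST) -> SelectorParams:
    X = np.asarray(X_train, float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("feature selection requires at least two classes")
    F, _ = f_classif(X, y_train)
    F = np.nan_to_num(F, nan=0.0)  # constant features carry no information
    k_eff = min(k, X.shape[1])
    order = np.lexsort((np.arange(len(F)), -F))  # descending F, index breaks ties
    selected = np.sort(order[:k_eff])
    return SelectorParams(k=k, selected=selected, f_statistic=F)


def apply_selector(X: np.ndarray, params: SelectorParams) -> np.ndarray:
    return np.asarray(X, float)[:, params.selected]
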