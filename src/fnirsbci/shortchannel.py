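"""Short-channel superficial-signal removal by Recursive Least Squares.

A 1.5 cm source-detector pair samples only extracerebral (scalp/skull)
hemodynamics.  Each probe side (lateral, medial) has one short channel; an
RLS adaptive filter per (side, chromophore) regresses that short channel
(plus an intercept) onto each of the side's three long channels.
Coefficients are learned on the training trials and applied frozen
thereafter, matching the real-time constraint that no test data may update
the filter.

RLS recursion (regressor x_t = [short_t, 1], target one long channel):

    k_t = P_{t-1} x_t / (λ + x_t' P_{t-1} x_t)
    e_t = y_t − w_{t-1}' x_t
    w_t = w_{t-1} + k_t e_t
    P_t = (P_{t-1} − k_t x_t' P_{t-1}) / λ

With forgetting factor λ = 1 and vanishing initialisation δ → 0+ this
converges to batch ordinary least squares on the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synth import (
    CHROMOPHORES,
    LONG_SIDES,
    SHORT_FOR_SIDE,
    REST,
    SessionRecording,
)

DEFAULT_FORGETTING = 0.999
DEFAULT_DELTA = 100.0


@dataclass
class RlsFilter:
    """One fitted filter: weights per long channel plus the shared P matrix."""

    weights: np.ndarray  # [n_targets, 2] — (slope, intercept) per long channel
    P: np.ndarray  # [2, 2] inverse-correlation matrix
    forgetting: float
    delta: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "P": self.P.tolist(),
            "forgetting": self.forgetting,
            "delta": self.delta,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RlsFilter":
        return cls(
            weights=np.asarray(d["weights"], float),
            P=np.asarray(d["P"], float),
            forgetting=float(d["forgetting"]),
            delta=float(d["delta"]),
            n_samples=int(d["n_samples"]),
        )


@dataclass
class RlsState:
    """One independent filter per (side, chromophore): 4 filters, each
    coupling a short channel to the 3 long channels of its side."""

    filters: dict[tuple[str, str], RlsFilter] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {f"{side}|{chrom}": f.to_dict() for (side, chrom), f in self.filters.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RlsState":
        filters = {}
        for key, fd in d.items():
            side, chrom = key.split("|")
            filters[(side, chrom)] = RlsFilter.from_dict(fd)
        return cls(filters)


def rls_fit(
    short_series: np.ndarray,
    long_series: np.ndarray,
    forgetting: float = DEFAULT_FORGETTING,
    delta: float = DEFAULT_DELTA,
) -> RlsFilter:
    """Run the RLS recursion over aligned training samples.

    ``long_series`` is [n, n_targets]; all targets share the regressor
    [short, 1] and therefore the same P, so the recursion is vectorised
    across targets.
    """
    short = np.asarray(short_series, float)
    Y = np.atleast_2d(np.asarray(long_series, float))
    if Y.shape[0] != short.shape[0]:
        Y = Y.T
    if Y.shape[0] != short.shape[0]:
        raise ValueError("short and long series must be aligned")
    if np.any(np.isnan(short)) or np.any(np.isnan(Y)):
        raise ValueError("NaN in RLS input")
    if not (0 < forgetting <= 1):
        raise ValueError("forgetting factor must be in (0, 1]")
    if delta <= 0:
        raise ValueError("delta must be positive")

    n, n_targets = Y.shape
    W = np.zeros((n_targets, 2))
    P = delta * np.eye(2)
    for t in range(n):
        x = np.array([short[t], 1.0])
        Px = P @ x
        k = Px / (forgetting + x @ Px)
        e = Y[t] - W @ x
        W += np.outer(e, k)
        P = (P - np.outer(k, Px)) / forgetting
        P = (P + P.T) / 2.0  # keep symmetric against round-off
    return RlsFilter(weights=W, P=P, forgetting=forgetting, delta=delta, n_samples=n)


def rls_apply(filt: RlsFilter, short_series: np.ndarray, long_series: np.ndarray) -> np.ndarray:
    """Subtract the predicted superficial contribution; coefficients frozen.

    Returns long − W·[short, 1] with the same shape as ``long_series``.
    """
    if filt.n_samples == 0:
        raise ValueError("RLS filter has not been fitted")
    short = np.asarray(short_series, float)
    Y = np.asarray(long_series, float)
    squeeze = Y.ndim == 1
    Y2 = np.atleast_2d(Y)
    if Y2.shape[0] != short.shape[0]:
        Y2 = Y2.T
    X = np.column_stack([short, np.ones_like(short)])
    out = Y2 - X @ filt.weights.T
    return out[:, 0] if squeeze else out


def _side_channel_indices(rec: SessionRecording, side: str, chrom: str) -> tuple[int, list[int]]:
    """(short channel index, long channel indices) for one side/chromophore."""
    short_side = SHORT_FOR_SIDE[side]
    short_idx = [i for i, c in enumerate(rec.channels) if c.side == short_side and c.kind == chrom]
    long_idx = [i for i, c in enumerate(rec.channels) if c.side == side and c.kind == chrom]
    if len(short_idx) != 1:
        raise ValueError(f"expected one short channel for {side}/{chrom}")
    return short_idx[0], sorted(long_idx, key=lambda i: rec.channels[i].position)


def fit_recording(
    rec: SessionRecording,
    forgetting: float = DEFAULT_FORGETTING,
    delta: float = DEFAULT_DELTA,
    include_rest: bool = False,
) -> RlsState:
    """Fit all per-(side, chromophore) filters on a training recording.

    Rest-period samples are excluded by default; the filters are trained on
    the concatenated task trials.
    """
    mask = np.ones(rec.n_samples, bool) if include_rest else rec.labels != REST
    state = RlsState()
    sides = sorted({c.side for c in rec.channels if c.side in LONG_SIDES})
    for side in sides:
        for chrom in CHROMOPHORES:
            s_idx, l_idx = _side_channel_indices(rec, side, chrom)
            state.filters[(side, chrom)] = rls_fit(
                rec.data[mask, s_idx], rec.data[np.ix_(mask, l_idx)], forgetting, delta
            )
    return state


def apply_recording(rec: SessionRecording, state: RlsState) -> SessionRecording:
    """Denoise every long channel with the frozen state; short channels kept."""
    data = rec.data.copy()
    sides = sorted({c.side for c in rec.channels if c.side in LONG_SIDES})
    for side in sides:
        for chrom in CHROMOPHORES:
            if (side, chrom) not in state.filters:
                raise ValueError(f"no fitted filter for {side}/{chrom}")
            s_idx, l_idx = _side_channel_indices(rec, side, chrom)
            data[:, l_idx] = rls_apply(
                state.filters[(side, chrom)], rec.data[:, s_idx], rec.data[:, l_idx]
            )
    return replace(rec, data=data)


def fit_concatenated(
    recs: list[SessionRecording],
    forgetting: float = DEFAULT_FORGETTING,
    delta: float = DEFAULT_DELTA,
    include_rest: bool = False,
) -> RlsState:
    """Fit filters over several recordings' task samples run back to back
    (the cross-participant training-cohort fit used by leave-one-out CV)."""
    if not recs:
        raise ValueError("no recordings to fit")
    state = RlsState()
    sides = sorted({c.side for c in recs[0].channels if c.side in LONG_SIDES})
    for side in sides:
        for chrom in CHROMOPHORES:
            shorts, longs = [], []
            for rec in recs:
                mask = np.ones(rec.n_samples, bool) if include_rest else rec.labels != REST
                s_idx, l_idx = _side_channel_indices(rec, side, chrom)
                shorts.append(rec.data[mask, s_idx])
                longs.append(rec.data[np.ix_(mask, l_idx)])
            state.filters[(side, chrom)] = rls_fit(
                np.concatenate(shorts), np.vstack(longs), forgetting, delta
            )
    return state
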