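"""Modified Beer-Lambert Law conversion and hemodynamic bandpass filtering.

Converts dual-wavelength (690/830 nm) raw intensities to changes in
oxygenated and deoxygenated hemoglobin concentration (ΔHbO, ΔHbR, µM) and
bandpass-filters the series to the 0.1-0.4 Hz hemodynamic band, which
isolates the response from cardiac and Mayer-wave oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import (
    CHROMOPHORES,
    HBO,
    HBR,
    MODE_DELTA_HB,
    MODE_RAW_INTENSITY,
    WAVELENGTHS_NM,
    ChannelInfo,
    ProbeLayout,
    SessionRecording,
)

# Hemoglobin extinction coefficients (cm^-1 mM^-1, base-10), Gratzer/Prahl
# compilation, at the device wavelengths.  Rows follow WAVELENGTHS_NM
# (690, 830), columns (HbO, HbR).
EXTINCTION_CM1_MM1 = {
    690: {HBO: 0.2760, HBR: 2.0520},
    830: {HBO: 0.9740, HBR: 0.6930},
}

#: differential pathlength factor, adult forehead, both wavelengths
DEFAULT_DPF = 6.0


def extinction_matrix() -> np.ndarray:
    """2x2 matrix E with E[i, j] = ε(λ_i, chromophore_j), cm^-1 mM^-1."""
    return np.array(
        [[EXTINCTION_CM1_MM1[wl][c] for c in CHROMOPHORES] for wl in WAVELENGTHS_NM]
    )


@dataclass(frozen=True)
class MbllParams:
    """Parameters of the Modified Beer-Lambert Law conversion.

    The baseline intensity I0(λ) is either the mean over ``baseline_window``
    (a sample slice) or given explicitly via ``baseline_i0`` (one value per
    wavelength) when the true baseline is known, e.g. for forward-modelled
    synthetic sessions.
    """

    dpf: float = DEFAULT_DPF
    baseline_window: tuple[int, int] | None = (0, 58)  # first ~10 s at 5.8 Hz
    baseline_i0: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dpf <= 0:
            raise ValueError("DPF must be positive")
        if self.baseline_window is None and self.baseline_i0 is None:
            raise ValueError("either baseline_window or baseline_i0 is required")


def mbll_convert(
    intensity_690: np.ndarray,
    intensity_830: np.ndarray,
    distance_cm: float,
    params: MbllParams = MbllParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Convert one position's dual-wavelength intensities to (ΔHbO, ΔHbR) in µM.

    ΔOD(λ,t) = −log10(I(λ,t) / I0(λ)); the 2x2 extinction system
    ΔOD = d·DPF·E·Δc is solved per sample, Δc returned in µM.
    """
    if distance_cm <= 0:
        raise ValueError("source-detector distance must be positive")
    I = np.column_stack([np.asarray(intensity_690, float), np.asarray(intensity_830, float)])
    if np.any(I <= 0):
        raise ValueError("intensities must be strictly positive")
    if params.baseline_i0 is not None:
        i0 = np.asarray(params.baseline_i0, float)
    else:
        a, b = params.baseline_window
        if b <= a or b > len(I):
            raise ValueError("baseline window empty or out of range")
        i0 = I[a:b].mean(axis=0)
    dod = -np.log10(I / i0)
    E = extinction_matrix()
    if abs(np.linalg.det(E)) < 1e-12:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    conc_mM = np.linalg.solve(E, dod.T).T / (distance_cm * params.dpf)
    conc_uM = conc_mM * 1000.0
    return conc_uM[:, 0], conc_uM[:, 1]


def convert_recording(
    rec: SessionRecording, layout: ProbeLayout, params: MbllParams | None = None
) -> SessionRecording:
    """MBLL-convert a RAW_INTENSITY recording to DELTA_HB (µM).

    When the recording carries its generating baseline intensities (synthetic
    forward-modelled sessions) and ``params`` does not specify a baseline,
    those are used, making the forward-inverse round trip exact.
    """
    if rec.mode != MODE_RAW_INTENSITY:
        raise ValueError("recording is not in RAW_INTENSITY mode")
    positions = sorted({c.position for c in rec.channels})
    channels: list[ChannelInfo] = []
    cols: list[np.ndarray] = []
    for pid in positions:
        i690 = rec.get_channel(pid, "690")
        i830 = rec.get_channel(pid, "830")
        side = next(c.side for c in rec.channels if c.position == pid)
        d = layout.position(pid).distance_cm
        p = params
        if p is None:
            if rec.baseline_intensity is not None:
                i0 = (
                    float(rec.baseline_intensity[rec.channel_index(pid, "690")]),
                    float(rec.baseline_intensity[rec.channel_index(pid, "830")]),
                )
                p = MbllParams(baseline_window=None, baseline_i0=i0)
            else:
                p = MbllParams()
        hbo, hbr = mbll_convert(i690, i830, d, p)
        channels.append(ChannelInfo(pid, side, HBO))
        cols.append(hbo)
        channels.append(ChannelInfo(pid, side, HBR))
        cols.append(hbr)
    return replace(
        rec,
        data=np.column_stack(cols),
        channels=tuple(channels),
        mode=MODE_DELTA_HB,
        baseline_intensity=None,
    )


# ---------------------------------------------------------------------------
# Bandpass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandpassSpec:
    """0.1-0.4 Hz Butterworth bandpass; causal single-pass for the real-time
    path, zero-phase forward-backward for offline analysis."""

    low_hz: float = 0.1
    high_hz: float = 0.4
    fs_hz: float = 5.8
    order: int = 3
    causal: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz < self.fs_hz / 2):
            raise ValueError("band must satisfy 0 < low < high < fs/2")

    def sos(self) -> np.ndarray:
        return signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=self.fs_hz, output="sos"
        )


def bandpass(series: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Filter a 1-D or [n_samples, n_channels] series to the hemodynamic band."""
    x = np.asarray(series, float)
    sos = spec.sos()
    warmup = 6 * spec.order + 1
    if x.shape[0] <= warmup:
        raise ValueError("series shorter than filter warm-up")
    if spec.causal:
        return signal.sosfilt(sos, x, axis=0)
    return signal.sosfiltfilt(sos, x, axis=0)


def bandpass_recording(rec: SessionRecording, spec: BandpassSpec | None = None) -> SessionRecording:
    """Bandpass every channel of a DELTA_HB recording."""
    if rec.mode != MODE_DELTA_HB:
        raise ValueError("bandpass operates on DELTA_HB recordings")
    spec = spec or BandpassSpec(fs_hz=rec.fs_hz)
    if spec.fs_hz != rec.fs_hz:
        spec = replace(spec, fs_hz=rec.fs_hz)
    return replace(rec, data=bandpass(rec.data, spec))
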