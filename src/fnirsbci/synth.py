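"""Seeded synthetic fNIRS sessions.

Emulates a single-detector prefrontal probe (six long source positions in a
lateral and a medial group of three, plus one 1.5 cm short source per group),
a three-group A/B task protocol with 2-minute rests, and the noise structure
typical of continuous-wave fNIRS: cardiac, respiratory and Mayer-wave
oscillations plus slow drift, shared between the short channel and the long
channels of its side, on top of a task-locked hemodynamic response.

Sessions are generated either as chromophore concentration changes
(``DELTA_HB``, µM) or forward-modelled to dual-wavelength raw intensities
(``RAW_INTENSITY``) by inverting the Modified Beer-Lambert Law, so the
conversion in :mod:`fnirsbci.hemo` can be validated against the generator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

# ---------------------------------------------------------------------------
# Constants: sides, tasks, channel kinds
# ---------------------------------------------------------------------------

LATERAL = "LATERAL"
MEDIAL = "MEDIAL"
SHORT_LATERAL = "SHORT_LATERAL"
SHORT_MEDIAL = "SHORT_MEDIAL"
LONG_SIDES = (LATERAL, MEDIAL)
SHORT_SIDES = (SHORT_LATERAL, SHORT_MEDIAL)
#: short-channel side serving each long side
SHORT_FOR_SIDE = {LATERAL: SHORT_LATERAL, MEDIAL: SHORT_MEDIAL}

TASK_A = "A"  # visualization (internally directed / DMN-proxy)
TASK_B = "B"  # workload (furniture selection / DLPFC-proxy)
REST = "REST"
TASKS = (TASK_A, TASK_B)

HBO = "HbO"
HBR = "HbR"
CHROMOPHORES = (HBO, HBR)

MODE_DELTA_HB = "DELTA_HB"
MODE_RAW_INTENSITY = "RAW_INTENSITY"

WAVELENGTHS_NM = (690, 830)


# ---------------------------------------------------------------------------
# Probe geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourcePosition:
    """One light-source position: id, probe side and source-detector distance."""

    id: int
    side: str
    distance_cm: float


@dataclass(frozen=True)
class ProbeLayout:
    """Optode geometry of the single usable detector.

    Six long positions (three lateral, three medial; four at 3.0 cm and the
    two furthest at 3.61 cm) and two short positions at 1.5 cm, one per side.
    ``short_map`` assigns each short position the three long positions of its
    side, the grouping used by the short-channel regression filters.
    """

    source_positions: tuple[SourcePosition, ...]
    short_map: dict[int, tuple[int, int, int]]
    wavelengths_nm: tuple[int, int] = WAVELENGTHS_NM
    detector_id: str = "B"

    def __post_init__(self) -> None:
        longs = [p for p in self.source_positions if p.side in LONG_SIDES]
        shorts = [p for p in self.source_positions if p.side in SHORT_SIDES]
        if len(longs) != 6 or len(shorts) != 2:
            raise ValueError("layout requires 6 long and 2 short source positions")
        for side in LONG_SIDES:
            if sum(p.side == side for p in longs) != 3:
                raise ValueError(f"expected 3 long positions on side {side}")
        if any(p.distance_cm != 1.5 for p in shorts):
            raise ValueError("short source-detector distance must be 1.5 cm")
        dists = sorted(p.distance_cm for p in longs)
        if dists[:4] != [3.0] * 4 or dists[4:] != [3.61] * 2:
            raise ValueError("long distances must be four 3.0 cm and two 3.61 cm")
        mapped = [pid for trip in self.short_map.values() for pid in trip]
        if sorted(mapped) != sorted(p.id for p in longs):
            raise ValueError("short_map must cover every long position exactly once")
        by_id = {p.id: p for p in self.source_positions}
        for sid, trip in self.short_map.items():
            short_side = by_id[sid].side
            want = LATERAL if short_side == SHORT_LATERAL else MEDIAL
            if any(by_id[pid].side != want for pid in trip):
                raise ValueError("short_map must pair a short source with its own side")

    @property
    def long_positions(self) -> tuple[SourcePosition, ...]:
        return tuple(p for p in self.source_positions if p.side in LONG_SIDES)

    @property
    def short_positions(self) -> tuple[SourcePosition, ...]:
        return tuple(p for p in self.source_positions if p.side in SHORT_SIDES)

    def position(self, pid: int) -> SourcePosition:
        for p in self.source_positions:
            if p.id == pid:
                return p
        raise KeyError(f"no source position {pid}")


def make_default_layout() -> ProbeLayout:
    """Default geometry: positions 1-3 lateral, 4-6 medial, 7/8 short."""
    positions = (
        SourcePosition(1, LATERAL, 3.0),
        SourcePosition(2, LATERAL, 3.0),
        SourcePosition(3, LATERAL, 3.61),
        SourcePosition(4, MEDIAL, 3.0),
        SourcePosition(5, MEDIAL, 3.0),
        SourcePosition(6, MEDIAL, 3.61),
        SourcePosition(7, SHORT_LATERAL, 1.5),
        SourcePosition(8, SHORT_MEDIAL, 1.5),
    )
    return ProbeLayout(positions, short_map={7: (1, 2, 3), 8: (4, 5, 6)})


# ---------------------------------------------------------------------------
# Task protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    task: str
    duration_s: float
    group: int
    split: str  # "train" or "test"


@dataclass(frozen=True)
class TaskProtocol:
    """Three groups of (task A, 120 s rest, task B, 120 s rest).

    The first two groups are the training split; the third is the held-out
    (real-time replay) split.
    """

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        for b in self.blocks:
            if b.task == REST and b.duration_s != REST_DURATION_S:
                raise ValueError("rest blocks must last 120 s")

    @property
    def total_duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    @property
    def train_groups(self) -> tuple[int, ...]:
        return tuple(sorted({b.group for b in self.blocks if b.split == "train"}))

    @property
    def test_groups(self) -> tuple[int, ...]:
        return tuple(sorted({b.group for b in self.blocks if b.split == "test"}))

    def block_samples(self, fs_hz: float) -> list[int]:
        """Samples per block: floor(duration x fs)."""
        return [int(np.floor(b.duration_s * fs_hz)) for b in self.blocks]

    def sample_arrays(self, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (labels, group indices); labels tile the axis exactly."""
        counts = self.block_samples(fs_hz)
        labels = np.concatenate(
            [np.full(n, b.task, dtype=object) for b, n in zip(self.blocks, counts)]
        ).astype(str)
        groups = np.concatenate(
            [np.full(n, b.group, dtype=int) for b, n in zip(self.blocks, counts)]
        )
        return labels, groups


REST_DURATION_S = 120.0
N_GROUPS = 3


def make_protocol(task_block_duration_s: float) -> TaskProtocol:
    """Build the 3-group protocol: each group A, rest(120 s), B, rest(120 s)."""
    if task_block_duration_s <= 0:
        raise ValueError("task block duration must be positive")
    blocks: list[Block] = []
    for g in range(N_GROUPS):
        split = "train" if g < 2 else "test"
        blocks += [
            Block(TASK_A, task_block_duration_s, g, split),
            Block(REST, REST_DURATION_S, g, split),
            Block(TASK_B, task_block_duration_s, g, split),
            Block(REST, REST_DURATION_S, g, split),
        ]
    return TaskProtocol(tuple(blocks))


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------

def _default_hbo_effect() -> dict[tuple[str, str], float]:
    # medial (DMN-proxy) positions respond preferentially to visualization,
    # lateral (DLPFC-proxy) positions to workload
    return {
        (LATERAL, TASK_A): 0.3,
        (LATERAL, TASK_B): 1.0,
        (MEDIAL, TASK_A): 1.0,
        (MEDIAL, TASK_B): 0.3,
    }


def _default_oscillations() -> dict[str, tuple[float, float]]:
    # name -> (amplitude µM, frequency Hz)
    return {
        "cardiac": (0.4, 1.1),
        "respiration": (0.2, 0.25),
        "mayer": (0.3, 0.1),
        "drift": (0.3, 0.01),
    }


@dataclass
class SessionConfig:
    """Everything needed to generate one participant's session.

    Amplitudes are µM of the task-locked response at its peak (HbO); the HbR
    response is ``hbr_ratio`` times the HbO one (inverted, smaller).
    ``superficial_gain`` couples the per-side superficial process (perfectly
    observed by that side's short channel) into each long channel.
    ``task_oscillation_gain`` sets the strength of the task-modulated
    in-band (0.1-0.4 Hz) cortical oscillation: sustained task engagement
    modulates the amplitude of low-frequency vasomotor activity, which is
    the part of the block response that survives the hemodynamic bandpass.
    Participant-level variability multiplies amplitudes, gains and noise sds
    by log-normal factors with sigma ``between_participant_sd``.
    """

    participant_id: str = "P00"
    seed: int | None = 0
    fs_hz: float = 5.8
    task_block_duration_s: float = 300.0
    hbo_effect_uM: dict[tuple[str, str], float] = field(default_factory=_default_hbo_effect)
    hbr_ratio: float = -0.3
    oscillations: dict[str, tuple[float, float]] = field(default_factory=_default_oscillations)
    task_oscillation_gain: float = 0.5
    white_sd_uM: float = 0.1
    superficial_gain: float = 0.5
    between_participant_sd: float = 0.3
    mode: str = MODE_DELTA_HB
    baseline_intensity: float = 1.0

    def __post_init__(self) -> None:
        if any(a < 0 for a, _ in self.oscillations.values()):
            raise ValueError("oscillation amplitudes must be non-negative")
        if self.white_sd_uM < 0 or self.superficial_gain < 0:
            raise ValueError("noise amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelInfo:
    """Channel metadata: source position, side, and HbO/HbR or wavelength."""

    position: int
    side: str
    kind: str  # "HbO" | "HbR" | "690" | "830"

    @property
    def name(self) -> str:
        return f"P{self.position}_{self.side}_{self.kind}"


@dataclass
class SessionRecording:
    """Multichannel session time series with per-sample task labels."""

    data: np.ndarray  # [n_samples, n_channels]
    channels: tuple[ChannelInfo, ...]
    fs_hz: float
    labels: np.ndarray  # per-sample task code
    groups: np.ndarray  # per-sample protocol group index
    participant_id: str
    mode: str
    baseline_intensity: np.ndarray | None = None  # per-channel, RAW mode

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.labels), len(self.channels)):
            raise ValueError("data shape inconsistent with labels/channels")
        if len(self.groups) != len(self.labels):
            raise ValueError("groups and labels must align")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def channel_index(self, position: int, kind: str) -> int:
        for i, c in enumerate(self.channels):
            if c.position == position and c.kind == kind:
                return i
        raise KeyError(f"no channel P{position} {kind}")

    def get_channel(self, position: int, kind: str) -> np.ndarray:
        return self.data[:, self.channel_index(position, kind)]

    def select_samples(self, mask: np.ndarray) -> "SessionRecording":
        return replace(
            self, data=self.data[mask], labels=self.labels[mask], groups=self.groups[mask]
        )

    def select_channels(self, idx: list[int]) -> "SessionRecording":
        bi = None if self.baseline_intensity is None else self.baseline_intensity[idx]
        return replace(
            self,
            data=self.data[:, idx],
            channels=tuple(self.channels[i] for i in idx),
            baseline_intensity=bi,
        )

    def copy(self) -> "SessionRecording":
        bi = None if self.baseline_intensity is None else self.baseline_intensity.copy()
        return replace(
            self,
            data=self.data.copy(),
            labels=self.labels.copy(),
            groups=self.groups.copy(),
            baseline_intensity=bi,
        )


def split_by_groups(
    rec: SessionRecording, groups: tuple[int, ...]
) -> SessionRecording:
    """Samples belonging to the given protocol groups (train/test split)."""
    return rec.select_samples(np.isin(rec.groups, groups))


# ---------------------------------------------------------------------------
# Hemodynamic response and generation
# ---------------------------------------------------------------------------

def double_gamma_hrf(fs_hz: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at fs: peak 6 s, undershoot 16 s,
    undershoot ratio 1/6, peak amplitude normalised to 1."""
    t = np.arange(int(np.floor(duration_s * fs_hz))) / fs_hz
    # gamma pdf with shape a, scale th peaks at (a-1)*th
    peak = _gamma_dist.pdf(t, a=6.0, scale=6.0 / 5.0)
    under = _gamma_dist.pdf(t, a=16.0, scale=16.0 / 15.0)
    h = peak - under / 6.0
    return h / h.max()


def task_response(labels: np.ndarray, task: str, fs_hz: float) -> np.ndarray:
    """Boxcar of the task convolved with the canonical HRF.

    The kernel is normalised to unit sum so a sustained block reaches a
    plateau of 1: an effect amplitude of ``a`` µM means the sustained
    response during that task's blocks is ``a`` µM."""
    boxcar = (labels == task).astype(float)
    hrf = double_gamma_hrf(fs_hz)
    return np.convolve(boxcar, hrf / hrf.sum())[: len(boxcar)]


def _superficial(
    n: int, fs_hz: float, osc: dict[str, tuple[float, float]], rng: np.random.Generator
) -> np.ndarray:
    """Sum of sinusoids (cardiac, respiration, Mayer, drift) with random phases.

    Synthesised directly at the sampled rate (band-limited synthesis): the
    1.1 Hz cardiac component is represented at its aliased position relative
    to the 5.8 Hz sampling, exactly as an analogue cardiac signal would
    appear after sampling without an anti-alias filter.
    """
    t = np.arange(n) / fs_hz
    out = np.zeros(n)
    for amp, f in osc.values():
        out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _band_limited_noise(n: int, fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to the 0.1-0.4 Hz band.

    Models ongoing cortical vasomotor activity; its amplitude is modulated
    by task engagement, which is the component of a sustained block response
    that survives the hemodynamic bandpass."""
    from scipy import signal as _sig

    sos = _sig.butter(3, [0.1, 0.4], btype="bandpass", fs=fs_hz, output="sos")
    x = _sig.sosfilt(sos, rng.standard_normal(n + 200))[200:]
    return x / x.std()


def generate_session(
    cfg: SessionConfig,
    layout: ProbeLayout | None = None,
    protocol: TaskProtocol | None = None,
) -> SessionRecording:
    """Generate one seeded synthetic session.

    In ``DELTA_HB`` mode each long channel is the task-locked response
    plus the shared per-side superficial process times ``superficial_gain``
    plus white noise; each short channel is the superficial process plus
    white noise, with no task-locked term. The task-locked response has two
    parts: the sustained component (canonical double-gamma HRF convolved
    with the task boxcar, scaled by the side/task/chromophore effect) and a
    task-modulated in-band oscillation (band-limited 0.1-0.4 Hz cortical
    noise whose amplitude follows the sustained response envelope times
    ``task_oscillation_gain``). In ``RAW_INTENSITY`` mode the ΔHb session
    is forward-modelled to 690/830 nm intensities around a baseline
    intensity.
    """
    if cfg.seed is None:
        raise ValueError("SessionConfig.seed must be set for reproducibility")
    if cfg.mode not in (MODE_DELTA_HB, MODE_RAW_INTENSITY):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    layout = layout or make_default_layout()
    protocol = protocol or make_protocol(cfg.task_block_duration_s)
    rng = np.random.default_rng(cfg.seed)

    labels, groups = protocol.sample_arrays(cfg.fs_hz)
    n = len(labels)

    # participant-level log-normal perturbations (drawn once per participant)
    def perturb() -> float:
        return float(np.exp(rng.normal(0.0, cfg.between_participant_sd)))

    effect = {k: v * perturb() for k, v in cfg.hbo_effect_uM.items()}
    white_sd = cfg.white_sd_uM * perturb()
    gain = {side: cfg.superficial_gain * perturb() for side in LONG_SIDES}

    responses = {task: task_response(labels, task, cfg.fs_hz) for task in TASKS}
    # one superficial process per side; HbR sees it scaled by hbr_ratio
    superficial = {side: _superficial(n, cfg.fs_hz, cfg.oscillations, rng) for side in LONG_SIDES}
    # per-side unit-variance band-limited (0.1-0.4 Hz) cortical noise whose
    # amplitude is modulated by the task response envelope
    band_noise = {side: _band_limited_noise(n, cfg.fs_hz, rng) for side in LONG_SIDES}
    chrom_scale = {HBO: 1.0, HBR: cfg.hbr_ratio}

    channels: list[ChannelInfo] = []
    cols: list[np.ndarray] = []
    for pos in layout.long_positions:
        for chrom in CHROMOPHORES:
            sustained = sum(
                effect[(pos.side, task)] * chrom_scale[chrom] * responses[task]
                for task in TASKS
            )
            envelope = np.clip(
                sum(effect[(pos.side, task)] * responses[task] for task in TASKS), 0.0, None
            )
            oscillation = (
                cfg.task_oscillation_gain
                * abs(chrom_scale[chrom])
                * envelope
                * band_noise[pos.side]
            )
            task_term = sustained + oscillation
            y = (
                task_term
                + gain[pos.side] * chrom_scale[chrom] * superficial[pos.side]
                + rng.normal(0.0, white_sd, n)
            )
            channels.append(ChannelInfo(pos.id, pos.side, chrom))
            cols.append(y)
    for pos in layout.short_positions:
        side = LATERAL if pos.side == SHORT_LATERAL else MEDIAL
        for chrom in CHROMOPHORES:
            y = chrom_scale[chrom] * superficial[side] + rng.normal(0.0, white_sd, n)
            channels.append(ChannelInfo(pos.id, pos.side, chrom))
            cols.append(y)

    rec = SessionRecording(
        data=np.column_stack(cols),
        channels=tuple(channels),
        fs_hz=cfg.fs_hz,
        labels=labels,
        groups=groups,
        participant_id=cfg.participant_id,
        mode=MODE_DELTA_HB,
    )
    if cfg.mode == MODE_RAW_INTENSITY:
        rec = delta_hb_to_intensity(rec, layout, cfg.baseline_intensity)
    return rec


def delta_hb_to_intensity(
    rec: SessionRecording, layout: ProbeLayout, baseline_intensity: float = 1.0
) -> SessionRecording:
    """Forward-model a ΔHb recording to dual-wavelength raw intensities.

    Inverts the Modified Beer-Lambert Law of :func:`fnirsbci.hemo.mbll_convert`:
    ΔOD(λ) = d·DPF·Σ_c ε(λ,c)·Δc, then I = I0·10^(−ΔOD).
    """
    from . import hemo  # local import to avoid a cycle at import time

    if rec.mode != MODE_DELTA_HB:
        raise ValueError("input recording must be in DELTA_HB mode")
    channels: list[ChannelInfo] = []
    cols: list[np.ndarray] = []
    i0: list[float] = []
    eps = hemo.extinction_matrix()  # rows: wavelengths, cols: (HbO, HbR), cm^-1 mM^-1
    positions = sorted({c.position for c in rec.channels})
    for pid in positions:
        pos = layout.position(pid)
        conc_mM = np.column_stack(
            [rec.get_channel(pid, HBO), rec.get_channel(pid, HBR)]
        ) / 1000.0  # µM -> mM
        dod = conc_mM @ eps.T * (pos.distance_cm * hemo.DEFAULT_DPF)
        for wi, wl in enumerate(WAVELENGTHS_NM):
            channels.append(ChannelInfo(pid, pos.side, str(wl)))
            cols.append(baseline_intensity * 10.0 ** (-dod[:, wi]))
            i0.append(baseline_intensity)
    return replace(
        rec,
        data=np.column_stack(cols),
        channels=tuple(channels),
        mode=MODE_RAW_INTENSITY,
        baseline_intensity=np.asarray(i0),
    )


def permute_task_blocks(rec: SessionRecording, seed: int) -> SessionRecording:
    """Shuffle A/B identities across task blocks, leaving the data untouched.

    The label-permutation null: window labels decouple from the hemodynamics
    while block structure, rest periods and group assignment are preserved.
    """
    rng = np.random.default_rng(seed)
    out = rec.copy()
    # contiguous runs of non-rest labels
    is_task = out.labels != REST
    edges = np.flatnonzero(np.diff(np.concatenate(([0], is_task.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    block_tasks = [out.labels[a] for a in starts]
    rng.shuffle(block_tasks)
    for a, b, task in zip(starts, stops, block_tasks):
        out.labels[a:b] = task
    return out


# ---------------------------------------------------------------------------
# I/O: CSV and SNIRF
# ---------------------------------------------------------------------------

_META_KEYS = ("fs_hz", "participant_id", "mode")


def write_session_csv(rec: SessionRecording, path) -> None:
    """One file per session: `time_s, P<pos>_<side>_<kind>..., label, group`
    preceded by `# key=value` metadata lines."""
    df = pd.DataFrame(rec.data, columns=rec.channel_names)
    df.insert(0, "time_s", rec.times_s)
    df["label"] = rec.labels
    df["group"] = rec.groups
    buf = io.StringIO()
    buf.write(f"# fs_hz={rec.fs_hz!r}\n")
    buf.write(f"# participant_id={rec.participant_id}\n")
    buf.write(f"# mode={rec.mode}\n")
    if rec.baseline_intensity is not None:
        vals = ",".join(repr(float(v)) for v in rec.baseline_intensity)
        buf.write(f"# baseline_intensity={vals}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_channel_name(name: str) -> ChannelInfo:
    try:
        pos, side, kind = name.split("_", 1)[0], name.split("_")[1:-1], name.split("_")[-1]
        side_name = "_".join(side)
        if side_name not in LONG_SIDES + SHORT_SIDES:
            raise ValueError
        if kind not in (HBO, HBR, "690", "830"):
            raise ValueError
        return ChannelInfo(int(pos[1:]), side_name, kind)
    except (ValueError, IndexError) as err:
        raise ValueError(f"unrecognised channel column {name!r}") from err


def read_session_csv(path) -> SessionRecording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"missing metadata lines: {missing}")
    if "label" not in df.columns or "group" not in df.columns:
        raise ValueError("session CSV must contain 'label' and 'group' columns")
    chan_cols = [c for c in df.columns if c not in ("time_s", "label", "group")]
    channels = tuple(_parse_channel_name(c) for c in chan_cols)
    bi = None
    if "baseline_intensity" in meta:
        bi = np.array([float(v) for v in meta["baseline_intensity"].split(",")])
    return SessionRecording(
        data=df[chan_cols].to_numpy(float),
        channels=channels,
        fs_hz=float(meta["fs_hz"]),
        labels=df["label"].to_numpy(str),
        groups=df["group"].to_numpy(int),
        participant_id=meta["participant_id"],
        mode=meta["mode"],
        baseline_intensity=bi,
    )


def write_session_snirf(rec: SessionRecording, path) -> None:
    """Minimal SNIRF (HDF5) export following the v1.0 layout.

    Chromophore channels are stored as processed concentration data
    (dataTypeLabel HbO/HbR); raw-intensity channels as CW amplitude with a
    wavelength index into ``probe/wavelengths``.
    """
    import h5py

    label_codes = {lab: i for i, lab in enumerate([REST, TASK_A, TASK_B])}
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.participant_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("Mode", data=rec.mode)
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=rec.data, dtype="f8")
        data1.create_dataset("time", data=rec.times_s, dtype="f8")
        for i, ch in enumerate(rec.channels, start=1):
            ml = data1.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=ch.position, dtype="i4")
            ml.create_dataset("detectorIndex", data=1, dtype="i4")
            if ch.kind in CHROMOPHORES:
                ml.create_dataset("dataType", data=99999, dtype="i4")  # processed
                ml.create_dataset("dataTypeLabel", data=ch.kind)
                ml.create_dataset("wavelengthIndex", data=1, dtype="i4")
            else:
                ml.create_dataset("dataType", data=1, dtype="i4")  # CW amplitude
                wl_idx = WAVELENGTHS_NM.index(int(ch.kind)) + 1
                ml.create_dataset("wavelengthIndex", data=wl_idx, dtype="i4")
            ml.create_dataset("sourcePower", data=1.0, dtype="f8")
            ml.create_dataset("side", data=ch.side)  # custom tag
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(WAVELENGTHS_NM, float))
        # stim groups: one per task, onset/duration/amplitude triplets
        codes = np.array([label_codes[l] for l in rec.labels])
        for si, task in enumerate(TASKS, start=1):
            stim = nirs.create_group(f"stim{si}")
            stim.create_dataset("name", data=task)
            onsets = []
            active = codes == label_codes[task]
            edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
            for a, b in zip(edges[::2], edges[1::2]):
                onsets.append([a / rec.fs_hz, (b - a) / rec.fs_hz, 1.0])
            stim.create_dataset("data", data=np.array(onsets, float))
        aux = nirs.create_group("aux1")
        aux.create_dataset("name", data="labels")
        aux.create_dataset("dataTimeSeries", data=codes.astype(float))
        aux.create_dataset("time", data=rec.times_s, dtype="f8")
        aux2 = nirs.create_group("aux2")
        aux2.create_dataset("name", data="groups")
        aux2.create_dataset("dataTimeSeries", data=rec.groups.astype(float))
        aux2.create_dataset("time", data=rec.times_s, dtype="f8")
        if rec.baseline_intensity is not None:
            nirs.create_dataset("baselineIntensity", data=rec.baseline_intensity)


def read_session_snirf(path) -> SessionRecording:
    import h5py

    code_labels = {0: REST, 1: TASK_A, 2: TASK_B}
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        data = np.asarray(nirs["data1/dataTimeSeries"])
        n_ch = data.shape[1]
        channels = []
        for i in range(1, n_ch + 1):
            ml = nirs[f"data1/measurementList{i}"]
            side = ml["side"][()].decode()
            src = int(ml["sourceIndex"][()])
            if int(ml["dataType"][()]) == 99999:
                kind = ml["dataTypeLabel"][()].decode()
            else:
                wl_idx = int(ml["wavelengthIndex"][()]) - 1
                kind = str(int(np.asarray(nirs["probe/wavelengths"])[wl_idx]))
            channels.append(ChannelInfo(src, side, kind))
        codes = np.asarray(nirs["aux1/dataTimeSeries"]).astype(int)
        labels = np.array([code_labels[c] for c in codes])
        groups = np.asarray(nirs["aux2/dataTimeSeries"]).astype(int)
        t = np.asarray(nirs["data1/time"])
        fs = 1.0 / float(np.median(np.diff(t)))
        bi = None
        if "baselineIntensity" in nirs:
            bi = np.asarray(nirs["baselineIntensity"])
        return SessionRecording(
            data=data,
            channels=tuple(channels),
            fs_hz=fs,
            labels=labels,
            groups=groups,
            participant_id=nirs["metaDataTags/SubjectID"][()].decode(),
            mode=nirs["metaDataTags/Mode"][()].decode(),
            baseline_intensity=bi,
        )


def write_session(rec: SessionRecording, path, format: str = "CSV") -> None:
    if format.upper() == "CSV":
        write_session_csv(rec, path)
    elif format.upper() == "SNIRF":
        write_session_snirf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_session(path, format: str = "CSV") -> SessionRecording:
    if format.upper() == "CSV":
        return read_session_csv(path)
    if format.upper() == "SNIRF":
        return read_session_snirf(path)
    raise ValueError(f"unknown format {format!r}")


def participant_seed(global_seed: int, participant_index: int) -> int:
    """Counter-based per-participant seed: adding a participant does not
    perturb the data of existing ones."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(participant_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_cohort(
    n_participants: int,
    global_seed: int,
    base_cfg: SessionConfig | None = None,
    layout: ProbeLayout | None = None,
    protocol: TaskProtocol | None = None,
) -> list[SessionRecording]:
    """Seeded cohort: participant i gets an independent substream of the seed."""
    base = base_cfg or SessionConfig()
    out = []
    for i in range(n_participants):
        cfg = replace(base, participant_id=f"P{i:02d}", seed=participant_seed(global_seed, i))
        out.append(generate_session(cfg, layout=layout, protocol=protocol))
    return out
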