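"""Reading, preprocessing, synchronization and epoching of EEG + kinematics.

EEG arrives either as EDF or as a delimited matrix with a one-line header of
channel labels (columns = channels, rows = samples).  Trajectories are
delimited files with header ``time,x,y,z`` (seconds, mm).  A ``SyncedTrial``
holds both signals restricted to their common time span: the EEG at the raw
rate (used for band decomposition) and decimated to the analysis rate (used
for decoding), with the trajectory interpolated onto the analysis grid.
"""

from __future__ import annotations

import csv
import json
import logging
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from bfndecode import edf as _edf

logger = logging.getLogger(__name__)

BUNDLE_VERSION = 1

#: The 25 scalp electrodes used for network analysis (10-20 layout).
ANALYSIS_ELECTRODES = (
    "FP1", "FP2", "F3", "FZ", "F4", "F8", "FT7", "FC3", "C3", "CZ", "C4",
    "CP3", "CPZ", "CP4", "P3", "PZ", "P4", "T3", "T5", "T4", "TP8", "T6",
    "O1", "OZ", "O2",
)

#: Recognized 10-20 scalp labels (superset of the analysis set).
KNOWN_1020_LABELS = frozenset(
    ANALYSIS_ELECTRODES
    + ("FP2", "F7", "F4", "FZ", "FC4", "FT8", "TP7", "P7", "P8", "POZ", "FPZ",
       "AFZ", "CZ", "PZ", "OZ", "T7", "T8", "F8")
)

#: Channels treated as auxiliary (reference / ocular), flagged but retained.
AUX_LABELS = frozenset({"A1", "A2", "M1", "M2", "HEOG", "VEOG", "EOG", "HEOL",
                        "HEOR", "VEOU", "VEOL", "EKG", "EMG"})

MODES = ("UD", "LR", "BF", "SPIRAL1", "SPIRAL2")


class AlignmentError(ValueError):
    """Raised when EEG and trajectory do not overlap in time."""


class ConfigurationError(ValueError):
    """Raised for invalid preprocessing / analysis settings."""


@dataclass
class EEGRecording:
    """Multichannel scalp EEG in microvolts, channels x time."""

    samples: np.ndarray
    rate: float = 1000.0
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0
    aux_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def pick(self, labels) -> "EEGRecording":
        """Return a copy restricted to ``labels`` (in the given order)."""
        idx = []
        for lab in labels:
            lab = lab.upper()
            if lab not in self.channel_labels:
                raise KeyError(f"channel {lab!r} not present")
            idx.append(self.channel_labels.index(lab))
        return replace(
            self,
            samples=self.samples[idx].copy(),
            channel_labels=[self.channel_labels[i] for i in idx],
            aux_channels=[a for a in self.aux_channels if a in labels],
        )


@dataclass
class TrajectoryRecording:
    """3-D hand position in mm sampled at ``rate`` Hz."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate: float = 120.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("times/x/y/z must have equal lengths")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def xyz(self) -> np.ndarray:
        return np.vstack([self.x, self.y, self.z])

    @property
    def start_time(self) -> float:
        return float(self.times[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])


@dataclass
class SyncedTrial:
    """EEG and trajectory restricted to their common span and epoched.

    ``eeg`` keeps the raw sampling rate (band decomposition needs it to
    resolve the upper gamma band); ``eeg_analysis`` is the anti-alias
    decimated version on the same grid as ``trajectory``.  ``epochs`` are
    ``(start, end)`` absolute-time windows of ``unit_s`` seconds.
    """

    eeg: EEGRecording
    trajectory: TrajectoryRecording
    mode: str
    analysis_rate: float = 100.0
    eeg_analysis: np.ndarray | None = None
    epochs: list[tuple[float, float]] = field(default_factory=list)
    unit_s: float | None = None
    features: dict | None = None  # filled by pipeline.compute_trial_features

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def epoch_slice_raw(self, i: int) -> np.ndarray:
        """Raw-rate EEG samples of epoch ``i`` with per-epoch baseline removed."""
        start, end = self.epochs[i]
        a = int(round((start - self.eeg.start_time) * self.eeg.rate))
        b = int(round((end - self.eeg.start_time) * self.eeg.rate))
        seg = self.eeg.samples[:, a:b]
        return seg - seg.mean(axis=1, keepdims=True)

    def epoch_index_of_sample(self, k: int) -> int:
        """Epoch index containing analysis-grid sample ``k`` (-1 if none)."""
        t = self.trajectory.times[k]
        for i, (s, e) in enumerate(self.epochs):
            if s - 1e-9 <= t < e - 1e-9 or (i == len(self.epochs) - 1 and abs(t - e) < 1e-9):
                return i
        return -1


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    notch_q: float = 35.0
    lowpass_hz: float = 55.0
    filter_order: int = 4
    analysis_rate: float = 100.0
    exclude_channels: tuple[str, ...] = ()


def _normalize_label(label: str) -> str:
    lab = label.strip().upper()
    if lab and lab not in KNOWN_1020_LABELS and lab not in AUX_LABELS:
        warnings.warn(f"unrecognized channel label {label!r}; passing through", stacklevel=3)
    return lab


def read_eeg(path, format: str | None = None, rate: float = 1000.0) -> EEGRecording:
    """Read an EEG file (EDF or delimited matrix with a label header row).

    Channel labels are normalized to upper case; reference/ocular channels
    are flagged in ``aux_channels`` rather than dropped.  For delimited
    files, which carry no rate metadata, ``rate`` supplies the sampling rate.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format not in ("edf", "csv"):
        raise ValueError(f"format must be 'edf' or 'csv', got {format!r}")

    if format == "edf":
        samples, rate, raw_labels = _edf.read_edf(path)
        labels = [_normalize_label(l) for l in raw_labels]
    else:
        with open(path, newline="") as fh:
            sniffed = fh.readline()
            delim = "\t" if "\t" in sniffed else ","
            labels = [_normalize_label(t) for t in sniffed.strip().split(delim)]
            rows = []
            for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
                if not row:
                    continue
                if len(row) != len(labels):
                    raise ValueError(
                        f"{path}: row {lineno} has {len(row)} fields, expected {len(labels)}"
                    )
                rows.append([float(v) for v in row])
        samples = np.asarray(rows, dtype=float).T

    aux = [l for l in labels if l in AUX_LABELS]
    return EEGRecording(samples=samples, rate=rate, channel_labels=labels, aux_channels=aux)


def write_eeg(path, rec: EEGRecording, format: str | None = None) -> None:
    """Write an :class:`EEGRecording` as EDF or a labelled delimited matrix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        _edf.write_edf(path, rec.samples, rec.rate, rec.channel_labels)
    else:
        with open(path, "w", newline="") as fh:
            fh.write(",".join(rec.channel_labels) + "\n")
            np.savetxt(fh, rec.samples.T, delimiter=",", fmt="%.10g")


def read_trajectory(path, rate: float = 120.0) -> TrajectoryRecording:
    """Read a delimited trajectory file with header ``time,x,y,z``."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline().strip().lower()
        delim = "\t" if "\t" in header else ","
        names = [t.strip() for t in header.split(delim)]
        if names[:4] != ["time", "x", "y", "z"]:
            raise ValueError(f"{path}: expected header time,x,y,z, got {names}")
        data = np.loadtxt(fh, delimiter=delim, ndmin=2)
    return TrajectoryRecording(
        times=data[:, 0], x=data[:, 1], y=data[:, 2], z=data[:, 3], rate=rate
    )


def write_trajectory(path, traj: TrajectoryRecording) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("time,x,y,z\n")
        np.savetxt(
            fh,
            np.column_stack([traj.times, traj.x, traj.y, traj.z]),
            delimiter=",",
            fmt="%.10g",
        )


def preprocess(eeg: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """DC removal, mains notch and zero-phase low-pass filtering.

    The band-pass of the recording chain is realized as per-channel mean
    subtraction (the 0 Hz corner) followed by a 4th-order Butterworth
    low-pass at ``lowpass_hz``, both applied forward-backward so the filter
    chain is zero phase.  A narrow IIR notch suppresses mains interference.
    """
    cfg = cfg or PreprocessConfig()
    if eeg.rate <= 2 * cfg.lowpass_hz:
        raise ConfigurationError(
            f"rate {eeg.rate} Hz too low for a {cfg.lowpass_hz} Hz low-pass"
        )
    rec = eeg
    if cfg.exclude_channels:
        keep = [l for l in rec.channel_labels if l not in set(cfg.exclude_channels)]
        rec = rec.pick(keep)

    data = rec.samples - rec.samples.mean(axis=1, keepdims=True)

    b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.rate)
    data = signal.filtfilt(b, a, data, axis=1)

    sos = signal.butter(cfg.filter_order, cfg.lowpass_hz, btype="low", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)

    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite samples after preprocessing")
    return replace(rec, samples=data)


def synchronize(
    eeg: EEGRecording, traj: TrajectoryRecording, analysis_rate: float = 100.0,
    mode: str = "UD",
) -> SyncedTrial:
    """Align EEG and trajectory on absolute timestamps.

    The common span is sampled on the analysis-rate grid: the trajectory is
    linearly interpolated onto it and the EEG is decimated with anti-alias
    filtering (polyphase resampling).  The raw-rate EEG is kept, cropped to
    the overlap, for band decomposition.
    """
    t0 = max(eeg.start_time, traj.start_time)
    t1 = min(eeg.end_time, traj.end_time)
    if t1 <= t0:
        raise AlignmentError(
            f"no temporal overlap: EEG [{eeg.start_time}, {eeg.end_time}] vs "
            f"trajectory [{traj.start_time}, {traj.end_time}]"
        )

    a = int(np.ceil((t0 - eeg.start_time) * eeg.rate - 1e-9))
    b = int(np.floor((t1 - eeg.start_time) * eeg.rate + 1e-9)) + 1
    cropped = replace(
        eeg,
        samples=eeg.samples[:, a:b].copy(),
        start_time=eeg.start_time + a / eeg.rate,
    )

    ratio = cropped.rate / analysis_rate
    up, down = 1, int(round(ratio))
    if abs(ratio - down) > 1e-9:
        from fractions import Fraction

        frac = Fraction(analysis_rate / cropped.rate).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
    eeg_analysis = signal.resample_poly(cropped.samples, up, down, axis=1)

    n = eeg_analysis.shape[1]
    grid = cropped.start_time + np.arange(n) / analysis_rate
    grid = grid[grid <= t1 + 1e-9]
    eeg_analysis = eeg_analysis[:, : len(grid)]

    traj_rs = TrajectoryRecording(
        times=grid,
        x=np.interp(grid, traj.times, traj.x),
        y=np.interp(grid, traj.times, traj.y),
        z=np.interp(grid, traj.times, traj.z),
        rate=analysis_rate,
    )
    return SyncedTrial(
        eeg=cropped, trajectory=traj_rs, mode=mode, analysis_rate=analysis_rate,
        eeg_analysis=eeg_analysis,
    )


def epoch(trial: SyncedTrial, unit_s: float = 2.0) -> SyncedTrial:
    """Partition the trial into contiguous non-overlapping ``unit_s`` windows.

    A trailing remainder shorter than ``unit_s`` is discarded (and logged);
    a trial shorter than one unit yields an empty epoch list with a warning.
    """
    if unit_s <= 0:
        raise ValueError("unit_s must be positive")
    t0 = trial.trajectory.start_time
    span = trial.trajectory.end_time - t0
    n = int(np.floor(span / unit_s + 1e-9))
    if n == 0:
        warnings.warn(f"trial span {span:.3f} s shorter than unit_s={unit_s}; no epochs")
    else:
        dropped = span - n * unit_s
        if dropped > 1e-9:
            logger.info("epoching dropped %.3f s trailing remainder", dropped)
    trial.epochs = [(t0 + i * unit_s, t0 + (i + 1) * unit_s) for i in range(n)]
    trial.unit_s = unit_s
    return trial


# ---------------------------------------------------------------------------
# Trial bundles: one directory per trial, all plain text (versioned).
# ---------------------------------------------------------------------------

def save_bundle(trial: SyncedTrial, out_dir) -> Path:
    """Write a trial to ``out_dir`` as meta.json + eeg.csv + trajectory.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": BUNDLE_VERSION,
        "mode": trial.mode,
        "eeg_rate": trial.eeg.rate,
        "eeg_start": trial.eeg.start_time,
        "analysis_rate": trial.analysis_rate,
        "unit_s": trial.unit_s,
        "epochs": trial.epochs,
        "channel_labels": trial.eeg.channel_labels,
        "aux_channels": trial.eeg.aux_channels,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    write_eeg(out / "eeg.csv", trial.eeg, format="csv")
    write_trajectory(out / "trajectory.csv", trial.trajectory)
    if trial.eeg_analysis is not None:
        np.savetxt(out / "eeg_analysis.csv", trial.eeg_analysis.T, delimiter=",", fmt="%.10g")
    return out


def load_bundle(bundle_dir) -> SyncedTrial:
    """Load a trial bundle written by :func:`save_bundle`."""
    d = Path(bundle_dir)
    meta = json.loads((d / "meta.json").read_text())
    if meta.get("version") != BUNDLE_VERSION:
        raise ValueError(f"{d}: unsupported bundle version {meta.get('version')}")
    eeg = read_eeg(d / "eeg.csv", format="csv", rate=meta["eeg_rate"])
    eeg.start_time = meta["eeg_start"]
    eeg.aux_channels = meta.get("aux_channels", [])
    traj = read_trajectory(d / "trajectory.csv", rate=meta["analysis_rate"])
    ea_path = d / "eeg_analysis.csv"
    eeg_analysis = np.loadtxt(ea_path, delimiter=",", ndmin=2).T if ea_path.exists() else None
    trial = SyncedTrial(
        eeg=eeg,
        trajectory=traj,
        mode=meta["mode"],
        analysis_rate=meta["analysis_rate"],
        eeg_analysis=eeg_analysis,
        epochs=[tuple(e) for e in meta.get("epochs", [])],
        unit_s=meta.get("unit_s"),
    )
    return trial
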