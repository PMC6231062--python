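"""Seeded synthetic EEG + trajectory generation with known ground truth.

Two families of trials are generated:

* single-axis oscillation trials (modes UD/LR/BF) whose EEG carries
  band-limited latent sources shared between planted electrode pairs with
  mode-dependent mixing, so the envelope-correlation networks differ across
  modes exactly where planted;
* spiral trials whose EEG channels are linear mixtures of the (normalized)
  trajectory coordinates, optionally with an epoch-level binary state that
  simultaneously scales the EEG gain and the planted connectivity — the
  regime in which a network-modulated decoder should beat the flat baseline.

Everything is driven by ``numpy.random.default_rng`` seeded from the config,
so identical configs produce bit-identical trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from bfndecode import io as _io
from bfndecode.bfn import BAND_BY_NAME

MODE_AXIS = {"UD": "z", "LR": "x", "BF": "y"}
_MODE_CODE = {"UD": 1, "LR": 2, "BF": 3, "SPIRAL1": 4, "SPIRAL2": 5}


@dataclass
class SyntheticConfig:
    seed: int = 0
    electrodes: tuple[str, ...] = _io.ANALYSIS_ELECTRODES
    rate: float = 1000.0
    traj_rate: float = 120.0
    analysis_rate: float = 100.0
    unit_s: float = 2.0
    preprocess: bool = False

    # mode-trial design
    n_trials_per_mode: int = 2
    n_epochs_per_trial: int = 5
    planted_bands: tuple[str, ...] = ("theta",)
    planted_pairs: tuple[tuple[str, str], ...] = ()
    coupling_by_mode: dict = field(default_factory=lambda: {"UD": 0.0, "LR": 0.0, "BF": 0.0})
    planted_amplitude: float = 3.0  # in-band amplitude relative to background

    # trajectory
    traj_amplitude_mm: float = 100.0
    traj_freq_hz: float = 0.5
    jitter_frac: float = 0.02

    # spiral-trial design
    spiral_radius_mm: float = 80.0
    spiral_turns: float = 3.0
    spiral_advance_mm: float = 200.0
    spiral_duration_s: float = 5.91
    n_spiral_repeats: int = 40

    # EEG composition / decoder ground truth
    noise_sd: float = 1.0
    eeg_gain: float = 2.0
    slope_modulation: float = 0.0  # blend weight of the state-1 mixing matrix
    state_coupling: tuple[float, float] = (0.1, 0.9)  # connectivity per state

    def __post_init__(self) -> None:
        for mode, c in self.coupling_by_mode.items():
            if not 0 <= c <= 1:
                raise ValueError(f"coupling for {mode} must be in [0, 1], got {c}")


def _rng(cfg: SyntheticConfig, *streams: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *streams])


def pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def band_noise(rng: np.random.Generator, n: int, rate: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance noise band-limited to [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _smooth_jitter(rng: np.random.Generator, n: int, rate: float, scale: float) -> np.ndarray:
    if scale == 0:
        return np.zeros(n)
    sos = signal.butter(2, min(1.0, rate / 4), btype="low", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return scale * x / max(x.std(), 1e-12)


def _epoch_states(rng: np.random.Generator, n_epochs: int) -> np.ndarray:
    return rng.integers(0, 2, size=n_epochs)


def _assemble_trial(
    cfg: SyntheticConfig, eeg_samples: np.ndarray, xyz: np.ndarray, t_traj: np.ndarray,
    mode: str,
) -> _io.SyncedTrial:
    eeg = _io.EEGRecording(
        samples=eeg_samples, rate=cfg.rate, channel_labels=list(cfg.electrodes)
    )
    if cfg.preprocess:
        eeg = _io.preprocess(eeg)
    traj = _io.TrajectoryRecording(
        times=t_traj, x=xyz[0], y=xyz[1], z=xyz[2], rate=cfg.traj_rate
    )
    trial = _io.synchronize(eeg, traj, analysis_rate=cfg.analysis_rate, mode=mode)
    return _io.epoch(trial, cfg.unit_s)


def _planted_pair_indices(cfg: SyntheticConfig) -> list[tuple[int, int]]:
    out = []
    for a, b in cfg.planted_pairs:
        out.append((cfg.electrodes.index(a.upper()), cfg.electrodes.index(b.upper())))
    return out


def _pair_components(pairs: list[tuple[int, int]]) -> list[set[int]]:
    comps: list[set[int]] = []
    for i, j in pairs:
        hits = [c for c in comps if i in c or j in c]
        merged = {i, j}.union(*hits) if hits else {i, j}
        comps = [c for c in comps if c not in hits] + [merged]
    return comps


def _inject_pair_sources(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    eeg: np.ndarray,
    couplings: np.ndarray,
) -> None:
    """Add band-limited latent sources to the planted electrodes, in place.

    Pairs sharing an electrode are merged into one component driven by a
    single shared source, so e.g. three pairs forming a triangle plant a
    coupled clique of three electrodes.  Each member receives
    ``sqrt(c) * shared + sqrt(1-c) * private`` in every planted band at
    ``planted_amplitude`` times the background level: pairwise signal
    correlation within a component is ~c and the marginal band power is
    coupling-independent.  ``couplings`` is a per-sample value in [0, 1]
    (may vary with the epoch state).
    """
    n = eeg.shape[1]
    c = np.clip(couplings, 0.0, 1.0)
    for band_name in cfg.planted_bands:
        band = BAND_BY_NAME[band_name]
        for comp in _pair_components(_planted_pair_indices(cfg)):
            shared = band_noise(rng, n, cfg.rate, band.lo, band.hi)
            for el in sorted(comp):
                private = band_noise(rng, n, cfg.rate, band.lo, band.hi)
                mix = np.sqrt(c) * shared + np.sqrt(1 - c) * private
                eeg[el] += cfg.planted_amplitude * cfg.noise_sd * mix


def generate_mode_trial(
    mode: str, cfg: SyntheticConfig, trial_index: int = 0
) -> _io.SyncedTrial:
    """One single-axis oscillation trial with mode-dependent planted coupling."""
    if mode not in MODE_AXIS:
        raise ValueError(f"mode must be one of {sorted(MODE_AXIS)}, got {mode!r}")
    rng = _rng(cfg, _MODE_CODE[mode], trial_index)
    duration = cfg.n_epochs_per_trial * cfg.unit_s
    n = int(round(duration * cfg.rate)) + 1  # inclusive endpoint covers all epochs

    eeg = cfg.noise_sd * np.vstack([pink_noise(rng, n) for _ in cfg.electrodes])
    coupling = float(cfg.coupling_by_mode.get(mode, 0.0))
    if cfg.planted_pairs:
        _inject_pair_sources(cfg, rng, eeg, np.full(n, coupling))

    t = np.arange(int(round(duration * cfg.traj_rate)) + 1) / cfg.traj_rate
    on_axis = cfg.traj_amplitude_mm * np.sin(2 * np.pi * cfg.traj_freq_hz * t)
    jit = cfg.jitter_frac * cfg.traj_amplitude_mm
    xyz = np.vstack(
        [_smooth_jitter(rng, len(t), cfg.traj_rate, jit) for _ in range(3)]
    )
    xyz["xyz".index(MODE_AXIS[mode])] = on_axis
    return _assemble_trial(cfg, eeg, xyz, t, mode)


def spiral_path(which: str, cfg: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Parametric spiral: a circle plus linear advance along one axis (mm)."""
    T = t[-1] if len(t) else 1.0
    phase = 2 * np.pi * cfg.spiral_turns * t / T
    adv = cfg.spiral_advance_mm * t / T
    r = cfg.spiral_radius_mm
    if which == "SPIRAL1":  # advance away from the body (y)
        return np.vstack([r * np.cos(phase), adv, r * np.sin(phase)])
    if which == "SPIRAL2":  # advance upward (z)
        return np.vstack([r * np.cos(phase), r * np.sin(phase), adv])
    raise ValueError(f"which must be SPIRAL1 or SPIRAL2, got {which!r}")


def generate_spiral_trial(
    which: str, cfg: SyntheticConfig, trial_index: int = 0, return_truth: bool = False
):
    """One spiral trial whose EEG mixes the trajectory coordinates.

    The channels carry a linear mixture of the z-scored coordinates through
    a subject-level mixing matrix, plus pink background noise.  With
    ``slope_modulation`` > 0, a per-epoch binary state blends in a second
    mixing matrix (so the true EEG-to-trajectory slopes are
    state-dependent) and the planted pair coupling switches with the state,
    letting the band networks reflect it.
    """
    rng = _rng(cfg, _MODE_CODE[which], trial_index)
    duration = cfg.spiral_duration_s
    n = int(round(duration * cfg.rate)) + 1
    t_eeg = np.arange(n) / cfg.rate

    xyz_eeg = spiral_path(which, cfg, t_eeg)
    coords_z = (xyz_eeg - xyz_eeg.mean(axis=1, keepdims=True)) / xyz_eeg.std(
        axis=1, keepdims=True
    )

    n_epochs = max(int(np.ceil(duration / cfg.unit_s)), 1)
    states = _epoch_states(rng, n_epochs)
    ep_of_sample = np.minimum((t_eeg / cfg.unit_s).astype(int), n_epochs - 1)
    m = states[ep_of_sample]

    # subject-level mixing: shared across a config's trials so models
    # generalize; the epoch state blends two mixing matrices, making the
    # true EEG->trajectory slopes state-dependent when slope_modulation > 0
    W0 = _rng(cfg, 99).standard_normal((len(cfg.electrodes), 3))
    W1 = W0 + _rng(cfg, 98).standard_normal(W0.shape)
    mixed = np.where(m == 1, cfg.slope_modulation, 0.0)
    eeg = cfg.eeg_gain * (
        (1 - mixed) * (W0 @ coords_z) + mixed * (W1 @ coords_z)
    )
    if cfg.noise_sd > 0:
        eeg += cfg.noise_sd * np.vstack([pink_noise(rng, n) for _ in cfg.electrodes])
    if cfg.planted_pairs:
        lo, hi = cfg.state_coupling
        _inject_pair_sources(cfg, rng, eeg, np.where(m == 1, hi, lo))

    t_traj = np.arange(int(round(duration * cfg.traj_rate)) + 1) / cfg.traj_rate
    xyz = spiral_path(which, cfg, t_traj)
    trial = _assemble_trial(cfg, eeg, xyz, t_traj, which)
    if return_truth:
        truth = {
            "W0": W0.tolist(),
            "W1": W1.tolist(),
            "states": states.tolist(),
            "slope_modulation": cfg.slope_modulation,
            "state_coupling": list(cfg.state_coupling),
            "planted_pairs": [list(p) for p in cfg.planted_pairs],
        }
        return trial, truth
    return trial


def generate_dataset(
    cfg: SyntheticConfig,
    preset: str = "experiment1",
    out_dir: str | Path | None = None,
):
    """Generate a set of trials plus a ground-truth record.

    Presets: ``experiment1`` (mode trials), ``experiment2`` (spiral
    repetitions), ``null`` (mode trials, identical coupling everywhere) and
    ``planted`` (mode trials with mode-dependent coupling).  Returns
    ``(trials, truth)``; bundles and ``truth.json`` are written when
    ``out_dir`` is given.
    """
    trials: list[_io.SyncedTrial] = []
    truth: dict = {"preset": preset, "seed": cfg.seed, "config": _config_record(cfg)}

    if preset in ("experiment1", "null", "planted"):
        for mode in ("UD", "LR", "BF"):
            for i in range(cfg.n_trials_per_mode):
                trials.append(generate_mode_trial(mode, cfg, trial_index=i))
        truth["planted_pairs"] = [list(p) for p in cfg.planted_pairs]
        truth["coupling_by_mode"] = dict(cfg.coupling_by_mode)
    elif preset == "experiment2":
        per_trial = []
        for which in ("SPIRAL1", "SPIRAL2"):
            for i in range(cfg.n_spiral_repeats):
                trial, tr = generate_spiral_trial(which, cfg, trial_index=i, return_truth=True)
                trials.append(trial)
                per_trial.append({"which": which, "index": i, **tr})
        truth["trials"] = per_trial
    else:
        raise ValueError(f"unknown preset {preset!r}")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, trial in enumerate(trials):
            _io.save_bundle(trial, out / f"trial_{i:03d}")
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return trials, truth


def _config_record(cfg: SyntheticConfig) -> dict:
    rec = asdict(cfg)
    rec["electrodes"] = list(cfg.electrodes)
    return rec
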