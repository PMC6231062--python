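"""Glue between ingestion, network construction and decoding."""

from __future__ import annotations

import pandas as pd

from bfndecode import bfn as _bfn
from bfndecode.io import SyncedTrial
from bfndecode.selection import DegreeSample


def compute_trial_features(
    trial: SyncedTrial,
    bands=None,
    target_cost: float = 0.18,
    wavelet_cfg: _bfn.WaveletConfig | None = None,
    electrodes: list[str] | None = None,
) -> SyncedTrial:
    """Build the per-(epoch, band) networks of a trial and attach features.

    Populates ``trial.features`` as ``{epoch: {band: NetworkFeatures}}``
    using the raw-rate EEG of each epoch (band decomposition needs the full
    bandwidth).  Returns the trial for chaining.
    """
    band_objs = [
        b if isinstance(b, _bfn.FrequencyBand) else _bfn.BAND_BY_NAME[b]
        for b in (bands if bands is not None else _bfn.BANDS)
    ]
    labels = electrodes or [
        l for l in trial.eeg.channel_labels if l not in trial.eeg.aux_channels
    ]
    rows = [trial.eeg.channel_labels.index(l) for l in labels]

    features: dict[int, dict] = {}
    for ep in range(trial.n_epochs):
        seg = trial.epoch_slice_raw(ep)[rows]
        features[ep] = {}
        for band in band_objs:
            env = _bfn.band_envelope(seg, trial.eeg.rate, band, wavelet_cfg, labels=labels)
            corr = _bfn.correlation_matrix(env)
            net = _bfn.build_bfn(corr, target_cost, band=band.name, epoch=ep)
            features[ep][band.name] = _bfn.network_features(net)
    trial.features = features
    return trial


def degree_samples(trials: list[SyncedTrial]) -> list[DegreeSample]:
    """Flatten per-epoch degree vectors of featured trials for selection."""
    out = []
    counter = 0
    for trial in trials:
        if trial.features is None:
            raise ValueError("trial has no features; run compute_trial_features() first")
        for ep, by_band in trial.features.items():
            for band, feats in by_band.items():
                out.append(
                    DegreeSample(
                        epoch=counter + ep,
                        mode=trial.mode,
                        band=band,
                        degrees=feats.DVector,
                        electrodes=_feature_labels(trial),
                    )
                )
        counter += trial.n_epochs
    return out


def _feature_labels(trial: SyncedTrial) -> list[str]:
    return [l for l in trial.eeg.channel_labels if l not in trial.eeg.aux_channels]


def metrics_frame(trials: list[SyncedTrial]) -> pd.DataFrame:
    """Tidy per-(trial, epoch, band) metric table for reporting/CLI."""
    rows = []
    for ti, trial in enumerate(trials):
        if trial.features is None:
            raise ValueError("trial has no features; run compute_trial_features() first")
        for ep, by_band in trial.features.items():
            for band, f in by_band.items():
                rows.append(
                    {
                        "trial": ti,
                        "mode": trial.mode,
                        "epoch": ep,
                        "band": band,
                        "VDegree": f.VDegree,
                        "VPLength": f.VPLength,
                        "Cluster": f.Cluster,
                        "Pbar": f.Pbar,
                    }
                )
    return pd.DataFrame(rows)
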