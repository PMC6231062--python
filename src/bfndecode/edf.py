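"""Minimal EDF (European Data Format) reader/writer.

Supports continuous multichannel recordings with a uniform sampling rate
across signals, which is all the pipeline needs.  The implementation follows
the published EDF header layout: a 256-byte fixed header, 256 bytes per
signal, then little-endian int16 data records scaled between the digital and
physical ranges declared per signal.
"""

from __future__ import annotations

import datetime
import os

import numpy as np

_HDR = 256

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; return (samples[channels, time], rate, labels)."""
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(_field(head, 236, 8))
        record_dur = float(_field(head, 244, 8))
        n_signals = int(_field(head, 252, 4))
        sig = fh.read(256 * n_signals)
        if len(sig) < 256 * n_signals:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def sfield(offset: int, width: int, i: int) -> str:
            start = offset * n_signals + i * width
            return sig[start : start + width].decode("ascii", errors="replace").strip()

        labels = [sfield(0, 16, i) for i in range(n_signals)]
        phys_min = [float(sfield(104, 8, i)) for i in range(n_signals)]
        phys_max = [float(sfield(112, 8, i)) for i in range(n_signals)]
        dig_min = [int(sfield(120, 8, i)) for i in range(n_signals)]
        dig_max = [int(sfield(128, 8, i)) for i in range(n_signals)]
        spr = [int(sfield(216, 8, i)) for i in range(n_signals)]

        if len(set(spr)) != 1:
            raise ValueError(f"{path}: mixed per-signal sampling rates are not supported")
        if record_dur <= 0:
            raise ValueError(f"{path}: non-positive record duration")
        rate = spr[0] / record_dur

        raw = np.fromfile(fh, dtype="<i2")

    expected = n_records * sum(spr)
    if raw.size < expected:
        raise ValueError(f"{path}: EDF data shorter than declared ({raw.size} < {expected})")
    # float before scaling: int16 arithmetic would overflow on - dig_min
    raw = raw[:expected].reshape(n_records, n_signals, spr[0]).astype(float)
    out = np.empty((n_signals, n_records * spr[0]), dtype=float)
    for i in range(n_signals):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        out[i] = (raw[:, i, :].reshape(-1) - dig_min[i]) * gain + phys_min[i]
    return out, rate, labels


def write_edf(
    path: str | os.PathLike,
    samples: np.ndarray,
    rate: float,
    labels: list[str],
    physical_dim: str = "uV",
) -> None:
    """Write (channels, time) data as a single-record-per-second EDF file.

    Trailing samples that do not fill a whole 1-second record are written as
    a final shorter record duration instead of being dropped only when the
    total length is below one second; otherwise the signal is zero-padded to
    a whole number of records (the pad is outside the declared time span of
    interest and is reproduced on read — callers that need exact round-trips
    should pass whole-second signals, which all bundled writers do).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be (channels, time)")
    n_signals, n_times = samples.shape
    if len(labels) != n_signals:
        raise ValueError("label count does not match channel count")

    spr = int(round(rate))
    if abs(spr - rate) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    if n_times % spr == 0 and n_times > 0:
        n_records, record_dur = n_times // spr, 1.0
    else:
        n_records, record_dur, spr = 1, n_times / rate, n_times

    phys_min = np.minimum(samples.min(axis=1), -1.0)
    phys_max = np.maximum(samples.max(axis=1), 1.0)

    now = datetime.datetime(2000, 1, 1)
    head = "".join(
        [
            "0".ljust(8),
            "X".ljust(80),
            "X".ljust(80),
            now.strftime("%d.%m.%y"),
            now.strftime("%H.%M.%S"),
            str(_HDR + 256 * n_signals).ljust(8),
            "".ljust(44),
            str(n_records).ljust(8),
            f"{record_dur:.6g}".ljust(8),
            str(n_signals).ljust(4),
        ]
    )

    def block(values: list[str], width: int) -> str:
        out = []
        for v in values:
            if len(v) > width:
                raise ValueError(f"EDF field too wide: {v!r}")
            out.append(v.ljust(width))
        return "".join(out)

    sig = "".join(
        [
            block([str(l)[:16] for l in labels], 16),
            block([""] * n_signals, 80),
            block([physical_dim] * n_signals, 8),
            block([f"{v:.6g}"[:8] for v in phys_min], 8),
            block([f"{v:.6g}"[:8] for v in phys_max], 8),
            block([str(_DIG_MIN)] * n_signals, 8),
            block([str(_DIG_MAX)] * n_signals, 8),
            block([""] * n_signals, 80),
            block([str(spr)] * n_signals, 8),
            block([""] * n_signals, 32),
        ]
    )

    data = np.zeros((n_records, n_signals, spr), dtype="<i2")
    for i in range(n_signals):
        gain = (phys_max[i] - phys_min[i]) / (_DIG_MAX - _DIG_MIN)
        padded = np.zeros(n_records * spr)
        padded[:n_times] = samples[i]
        dig = np.round((padded - phys_min[i]) / gain) + _DIG_MIN
        data[:, i, :] = dig.reshape(n_records, spr).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head.encode("ascii"))
        fh.write(sig.encode("ascii"))
        data.tofile(fh)
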