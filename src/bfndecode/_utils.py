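"""Small shared helpers."""

from __future__ import annotations

import decimal

import numpy as np


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed-table conventions.

    Python's builtin ``round`` uses banker's rounding, which disagrees with
    the half-up convention used by the reference tables (e.g. 0.51254 must
    round to 0.5125, 0.0455 to 0.046 at 3 digits).
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def sample_sd(values) -> float:
    """Sample standard deviation (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("sample SD needs at least two values")
    return float(np.std(arr, ddof=1))


def as_1d_float(x, name: str = "array") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr
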