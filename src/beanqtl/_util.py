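"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Report tables use half-up rounding (68.385 -> 68.39), unlike Python's
    banker's rounding. A tiny relative epsilon absorbs binary representation
    error in values that are exact halves in decimal.
    """
    if not np.isfinite(x):
        return float(x)
    scale = 10.0**ndigits
    scaled = x * scale
    eps = 1e-9 * max(1.0, abs(scaled))
    if scaled >= 0:
        return math.floor(scaled + 0.5 + eps) / scale
    return -math.floor(-scaled + 0.5 + eps) / scale


def check_probability(name: str, value: float, *, open_interval: bool = False) -> None:
    lo_ok = value > 0 if open_interval else value >= 0
    hi_ok = value < 1 if open_interval else value <= 1
    if not (lo_ok and hi_ok):
        raise ValueError(f"{name}={value!r} is not a valid probability")
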