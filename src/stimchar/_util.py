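"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero for positive x.

    Frame counts and step sizes are non-negative throughout the package,
    so only the positive convention matters: 0.5 -> 1, 1.5 -> 2.
    """
    return math.floor(x + 0.5)


def clamp(x: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, x))
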