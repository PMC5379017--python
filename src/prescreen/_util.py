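"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (70.5 -> 71, -0.5 -> -1).

    Python's built-in ``round`` rounds half to even; printed clinical tables
    round half away from zero.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
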