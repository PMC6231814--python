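"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero at positive values (half-up).

    Used everywhere a displayed percentage or grid value is rounded, so
    51.25% at 1 decimal is 51.3, not banker's 51.2.
    """
    if math.isnan(value):
        return value
    factor = 10.0**decimals
    return math.floor(value * factor + 0.5) / factor
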