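"""Shared unit constants and the report rounding policy.

All internal speeds are m·s⁻¹, VO2 in mL·kg⁻¹·min⁻¹, costs per meter.  The
single min→s bridge (60 s·min⁻¹) lives here so oxygen cost is always
``vo2 / (speed · SEC_PER_MIN)`` in mL·kg⁻¹·m⁻¹.
"""

from __future__ import annotations

import math

#: seconds per minute — bridges VO2 (per minute) and speed (per second)
SEC_PER_MIN = 60.0

#: joules per thermochemical kilocalorie-per-litre, i.e. per cal·mL⁻¹
JOULE_PER_CAL = 4.184

#: m·s⁻¹ per km·h⁻¹
MS_PER_KMH = 1.0 / 3.6


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report-table convention).

    Python's built-in ``round`` uses banker's rounding (2.835 → 2.83 at two
    decimals); descriptive tables in sports science round half away from
    zero (2.835 → 2.84), so report formatting goes through this helper.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    # nudge by one ulp so values that are exact halves after a decimal
    # product (e.g. 2.835 stored as 2.83499999...) round as printed
    nudged = scaled + math.copysign(1e-9, scaled) if scaled else 0.0
    return math.copysign(math.floor(abs(nudged) + 0.5), x) / scale


def kmh_to_ms(v_kmh: float) -> float:
    return v_kmh * MS_PER_KMH


def ms_to_kmh(v_ms: float) -> float:
    return v_ms / MS_PER_KMH
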