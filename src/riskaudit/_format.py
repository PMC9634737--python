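"""Presentation-only rounding and cell formatting for rendered reports.

Internally all estimates keep full precision; reports round half-up —
metrics to 2 decimals, O/E to 1 — and print fraction metrics with their
numerator and denominator ("0.37 (25/68)").  Undefined values render as
"nan (0/0)" with an "N/A" interval, and an infinite O/E as "inf".
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    if math.isnan(x) or math.isinf(x):
        return x
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def fmt_value(x: float, ndigits: int = 2) -> str:
    if math.isnan(x):
        return "nan"
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    s = f"{round_half_up(x, ndigits):.{ndigits}f}"
    if ndigits >= 2 and s.endswith("0"):
        s = s[:-1]  # "0.20" prints as "0.2", "1.00" as "1.0"
    return s


def fmt_fraction(value: float, numerator, denominator, ndigits: int = 2) -> str:
    num = 0 if numerator is None else numerator
    den = 0 if denominator is None else denominator
    return f"{fmt_value(value, ndigits)} ({num}/{den})"


def fmt_ci(ci_low: float, ci_high: float, ndigits: int = 2) -> str:
    if math.isnan(ci_low) or math.isnan(ci_high):
        return "N/A"
    return f"[{fmt_value(ci_low, ndigits)}, {fmt_value(ci_high, ndigits)}]"


def fmt_oe(ratio: float, observed: int, expected: float) -> str:
    return f"{fmt_value(ratio, 1)} ({observed}/{expected:.1f})"
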