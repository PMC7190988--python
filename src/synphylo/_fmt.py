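"""Centralised percentage rounding so every report table agrees."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, decimals: int = 1) -> float:
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * count / total, decimals)


def adaptive_percent(count: float, total: float) -> float:
    """Printed-style percentage: 2 decimals below 1%, 1 decimal below 10%,
    integer otherwise."""
    raw = 100.0 * count / total
    if raw < 1.0:
        return round_half_up(raw, 2)
    if raw < 10.0:
        return round_half_up(raw, 1)
    return round_half_up(raw, 0)
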