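"""Small shared helpers: half-up rounding and NA-aware formatting."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

NA = None  # undefined-metric marker (zero denominator); serializes as "NA"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as clinical tables print.

    Python's built-in round() is banker's rounding and would print 28.5% as
    28; report percentages here follow the half-up convention instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(v)


def pct_int(numerator: int, denominator: int) -> int:
    """Integer display percentage (half-up). Requires denominator > 0."""
    if denominator <= 0:
        raise ValueError("percentage with non-positive denominator")
    return int(round_half_up(100.0 * numerator / denominator))


def fmt_metric(value, ndigits: int = 2) -> str:
    """Format a proportion for human tables; undefined values print as NA."""
    if value is NA:
        return "NA"
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
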