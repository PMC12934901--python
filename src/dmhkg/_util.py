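"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention of reported percentages (e.g. 92.05 -> 92.1).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(part: float, total: float, ndigits: int = 1) -> float:
    """Percentage ``part / total * 100`` rounded half-up to ``ndigits``."""
    if total <= 0:
        raise ValueError("percentage undefined for non-positive total")
    return round_half_up(part / total * 100.0, ndigits)
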