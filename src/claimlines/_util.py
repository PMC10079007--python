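"""Small shared helpers: day-granular date arithmetic and reporting rounding."""

from __future__ import annotations

import datetime as dt
from decimal import Decimal, ROUND_HALF_UP

DAYS_PER_MONTH = 30.4375  # 365.25 / 12; used only for reporting durations
BASELINE_DAYS = 365       # "12 months" baseline window
POST_SCT_WINDOW_DAYS = 122  # "4 months" after transplant

__all__ = [
    "DAYS_PER_MONTH",
    "BASELINE_DAYS",
    "POST_SCT_WINDOW_DAYS",
    "round_half_up",
    "days_to_months",
    "as_date",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's built-in ``round`` is banker's rounding; reported percentages
    use half-up (e.g. 0.25 -> 0.3 at one decimal).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


def as_date(value) -> dt.date:
    """Coerce ISO strings / datetimes / pandas timestamps to datetime.date."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if hasattr(value, "to_pydatetime"):  # pandas Timestamp
        return value.to_pydatetime().date()
    return dt.date.fromisoformat(str(value)[:10])
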