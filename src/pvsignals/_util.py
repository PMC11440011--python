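"""Small shared helpers: calendar-quarter labels and report rounding."""
from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


def quarter_key(label: str) -> tuple[int, int]:
    """Sortable (year, quarter) key for a ``YYYYQn`` label.

    Raises ValueError for anything that does not match the pattern.
    """
    m = _QUARTER_RE.match(label)
    if m is None:
        raise ValueError(f"invalid quarter label {label!r}; expected e.g. '2020Q1'")
    return int(m.group(1)), int(m.group(2))


def is_quarter_label(label: str) -> bool:
    return _QUARTER_RE.match(label) is not None


def quarter_range(first: str, last: str) -> list[str]:
    """Inclusive list of quarter labels from ``first`` to ``last``."""
    y0, q0 = quarter_key(first)
    y1, q1 = quarter_key(last)
    if (y0, q0) > (y1, q1):
        raise ValueError(f"quarter range start {first} after end {last}")
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tables in reports are printed.

    Python's builtin round() is banker's rounding; report layouts use
    conventional half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
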