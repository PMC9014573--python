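"""Small shared helpers."""

from __future__ import annotations

import math
import re


def round_half_up(x: float) -> int:
    """Round a non-negative value to the nearest integer, halves upward.

    Python's built-in ``round`` uses banker's rounding; published workforce
    tables round 0.5 up, so percentage cells are reproduced with this rule.
    """
    if x < 0:
        raise ValueError("round_half_up is defined for non-negative values")
    return int(math.floor(x + 0.5))


_WS = re.compile(r"\s+")


def normalize_title(title: str) -> str:
    """Canonical form of a raw position title: trimmed, single-spaced,
    case-folded, with spacing around '/' removed."""
    s = _WS.sub(" ", str(title).strip())
    s = re.sub(r"\s*/\s*", "/", s)
    return s.casefold()


class StepSeries:
    """Right-continuous step function over years.

    Built from ``{year: value}`` breakpoints or a scalar; ``at(year)`` returns
    the value at the greatest breakpoint <= year, or the earliest value for
    years before the first breakpoint.
    """

    def __init__(self, values: "float | dict[int, float]"):
        if isinstance(values, dict):
            if not values:
                raise ValueError("empty year series")
            self._points = sorted(values.items())
        else:
            self._points = [(0, float(values))]

    def at(self, year: int) -> float:
        out = self._points[0][1]
        for y, v in self._points:
            if y <= year:
                out = v
            else:
                break
        return out

    def first_year(self) -> int:
        return self._points[0][0]
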