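"""Calendar-quarter labels ("2018Q2") and arithmetic on them.

Spontaneous-report bundles are organised by calendar quarter; all period
logic in the package goes through these helpers so that quarter ordering,
ranges and date conversion are defined in exactly one place.
"""

from __future__ import annotations

import re

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

# first month of each quarter
_Q_START_MONTH = {1: 1, 2: 4, 3: 7, 4: 10}


def quarter_index(label: str) -> int:
    """Map a quarter label to a sortable integer (1999Q1 -> 7996)."""
    m = _QUARTER_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"invalid quarter label: {label!r} (expected e.g. '2018Q2')")
    year, q = int(m.group(1)), int(m.group(2))
    return year * 4 + (q - 1)


def quarter_label(index: int) -> str:
    """Inverse of :func:`quarter_index`."""
    year, q = divmod(int(index), 4)
    return f"{year}Q{q + 1}"


def quarter_range(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels from *start* to *end*."""
    i, j = quarter_index(start), quarter_index(end)
    if i > j:
        raise ValueError(f"inverted quarter bounds: {start} > {end}")
    return [quarter_label(k) for k in range(i, j + 1)]


def quarter_start_date(label: str) -> str:
    """YYYYMMDD of the first day of the quarter."""
    m = _QUARTER_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"invalid quarter label: {label!r}")
    year, q = int(m.group(1)), int(m.group(2))
    return f"{year}{_Q_START_MONTH[q]:02d}01"


def quarter_of_date(yyyymmdd: str) -> str:
    """Quarter label containing a YYYYMMDD date string."""
    s = str(yyyymmdd).strip()
    if len(s) != 8 or not s.isdigit():
        raise ValueError(f"invalid date: {yyyymmdd!r} (expected YYYYMMDD)")
    year, month = int(s[:4]), int(s[4:6])
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month in date {yyyymmdd!r}")
    return f"{year}Q{(month - 1) // 3 + 1}"
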