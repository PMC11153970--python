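"""Strict date/time coercion for workbook cells and raw-event fields.

Only unambiguous representations are accepted: native date/datetime cells
(what openpyxl yields for date-formatted Excel cells) and ISO 8601 strings.
Ambiguous text such as ``03/04/2021`` is rejected rather than guessed —
a silently misread date would corrupt every downstream denominator.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd


def is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, str):
        return value.strip() == ""
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def coerce_timestamp(value) -> dt.datetime:
    """Return a datetime from a cell value; raise ValueError if ambiguous."""
    if isinstance(value, pd.Timestamp):
        return value.to_pydatetime()
    if isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.date):
        return dt.datetime(value.year, value.month, value.day)
    if isinstance(value, str):
        text = value.strip()
        try:
            return dt.datetime.fromisoformat(text)
        except ValueError:
            raise ValueError(f"not an ISO 8601 date/time: {value!r}") from None
    raise ValueError(f"cannot interpret {value!r} as a date/time")


def coerce_date(value) -> dt.date:
    """Return a calendar date from a cell value; raise ValueError if ambiguous."""
    return coerce_timestamp(value).date()


def coerce_id(value) -> str:
    """Normalise an alphanumeric identifier cell to a string.

    Numeric cells (Excel stores ``101`` as a float) become their integer
    repr so that ``101`` in one sheet matches ``"101"`` in another.
    """
    if isinstance(value, str):
        return value.strip()
    if isinstance(value, bool) or value is None:
        raise ValueError(f"not an identifier: {value!r}")
    if isinstance(value, float):
        if value.is_integer():
            return str(int(value))
        raise ValueError(f"not an identifier: {value!r}")
    if isinstance(value, int):
        return str(value)
    raise ValueError(f"not an identifier: {value!r}")


def coerce_int(value) -> int:
    """Coerce a cell to an exact integer (1.0 -> 1, '2' -> 2, 1.5 -> error)."""
    if isinstance(value, bool):
        raise ValueError(f"not an integer: {value!r}")
    if isinstance(value, int):
        return value
    if isinstance(value, float):
        if value.is_integer():
            return int(value)
        raise ValueError(f"not an integer: {value!r}")
    if isinstance(value, str):
        try:
            return int(value.strip())
        except ValueError:
            raise ValueError(f"not an integer: {value!r}") from None
    raise ValueError(f"not an integer: {value!r}")


def date_range(start: dt.date, end: dt.date) -> list[dt.date]:
    """All dates in the closed interval [start, end]."""
    n = (end - start).days + 1
    return [start + dt.timedelta(days=i) for i in range(max(n, 0))]
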