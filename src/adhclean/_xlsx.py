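"""Deterministic XLSX writing.

openpyxl stamps workbooks with the wall clock (document properties and zip
entry timestamps), which breaks byte-level reproducibility of runs with a
fixed seed. ``save_workbook`` pins both so identical content yields
identical bytes.
"""

from __future__ import annotations

import datetime as dt
import io
import zipfile
from pathlib import Path

from openpyxl import Workbook

_EPOCH = dt.datetime(2000, 1, 1)
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)

DATE_FORMAT = "yyyy-mm-dd"


def save_workbook(wb: Workbook, path: str | Path) -> None:
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    buf = io.BytesIO()
    wb.save(buf)
    Path(path).write_bytes(_rezip(buf.getvalue()))


def _rezip(data: bytes) -> bytes:
    out = io.BytesIO()
    with zipfile.ZipFile(io.BytesIO(data)) as zin:
        with zipfile.ZipFile(out, "w", zipfile.ZIP_DEFLATED) as zout:
            for name in sorted(zin.namelist()):
                info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
                info.compress_type = zipfile.ZIP_DEFLATED
                info.external_attr = 0o600 << 16
                zout.writestr(info, zin.read(name))
    return out.getvalue()


def append_row(ws, values, date_columns: set[int] = frozenset()) -> None:
    """Append one row; format the given 1-based columns as date cells."""
    ws.append(values)
    if date_columns:
        r = ws.max_row
        for c in date_columns:
            ws.cell(row=r, column=c).number_format = DATE_FORMAT
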