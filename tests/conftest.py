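import datetime as dt
from pathlib import Path

import pytest
from openpyxl import Workbook

D = dt.date  # shorthand in fixtures


def make_workbook(path: Path, sheets: dict[str, list[list]]) -> Path:
    """Write a workbook from {sheet name: [header, *rows]} literals."""
    wb = Workbook()
    wb.remove(wb.active)
    for name, rows in sheets.items():
        ws = wb.create_sheet(name)
        for row in rows:
            ws.append(row)
    wb.save(path)
    return path


def write_csv(path: Path, lines: list[str]) -> Path:
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def minimal_sheets():
    """Smallest well-formed auxiliary content: one monitor, one regimen."""
    return {
        "EMInfo": [
            ["PatientCode", "Monitor", "StartDate", "EndDate"],
            ["P01", "M1", D(2021, 5, 1), D(2021, 5, 10)],
        ],
        "Regimen": [
            ["PatientCode", "Monitor", "ExpectedOpenings", "StartDate",
             "EndDate", "On", "Off"],
            ["P01", "M1", 1, D(2021, 5, 1), D(2021, 5, 10), None, None],
        ],
    }


@pytest.fixture
def minimal_fixture(tmp_path, minimal_sheets):
    """Auxiliary workbook + raw folder with one matching events file."""
    aux = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
    raw = tmp_path / "raw"
    raw.mkdir()
    write_csv(raw / "p01_eventslist.csv",
              ["PatientCode,Monitor,Date"] +
              [f"P01,M1,2021-05-{d:02d} 08:00:00" for d in range(1, 11)])
    return aux, raw
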