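"""Error/warning taxonomy shared by every pipeline stage.

Findings are partitioned into *critical errors* — problems that would make
the implementation calculation wrong (bad dates, missing mandatory data,
regimen coverage defects) and therefore block output — and *warnings* —
inconsistencies the investigator should review but that never block output
(e.g. a declared monitor with no raw data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

# -- critical error codes ----------------------------------------------------
MISSING_SHEET = "MISSING_SHEET"
MISSING_COLUMN = "MISSING_COLUMN"
BAD_DATE = "BAD_DATE"
BAD_VALUE = "BAD_VALUE"
DATE_ORDER = "DATE_ORDER"
DUPLICATE_MONITOR = "DUPLICATE_MONITOR"
ON_OFF_PAIR = "ON_OFF_PAIR"
ORPHAN_ROW = "ORPHAN_ROW"
REGIMEN_GAP = "REGIMEN_GAP"
REGIMEN_OVERLAP = "REGIMEN_OVERLAP"
NO_RAW_FILES = "NO_RAW_FILES"
UNREADABLE_FILE = "UNREADABLE_FILE"

# -- warning codes -----------------------------------------------------------
NO_RAW_DATA = "NO_RAW_DATA"
UNDECLARED_MONITOR = "UNDECLARED_MONITOR"
IGNORED_FILE = "IGNORED_FILE"
DUPLICATE_EVENT = "DUPLICATE_EVENT"
ADJUST_OUT_OF_WINDOW = "ADJUST_OUT_OF_WINDOW"
ZERO_DELTA = "ZERO_DELTA"
NEGATIVE_CLAMP = "NEGATIVE_CLAMP"
NMP_CLIPPED = "NMP_CLIPPED"
NMP_OUT_OF_WINDOW = "NMP_OUT_OF_WINDOW"
UNKNOWN_KEY = "UNKNOWN_KEY"
ZERO_DENOMINATOR = "ZERO_DENOMINATOR"


@dataclass(frozen=True, order=True)
class Finding:
    """One validation finding, attributed to a sheet or file and a row.

    ``row`` is the 1-based row number in the source sheet/file (header = row
    1), or ``None`` when the finding concerns a whole sheet or folder.
    """

    location: str
    row: int | None
    code: str
    message: str

    def render(self) -> str:
        row = "" if self.row is None else str(self.row)
        return f"{self.code}\t{self.location}\t{row}\t{self.message}"


def _sort_key(f: Finding):
    return (f.location, f.row if f.row is not None else 0, f.code, f.message)


@dataclass
class ValidationReport:
    """Accumulated critical errors and warnings for one pipeline run.

    The pipeline refuses to emit the implementation workbook while
    ``errors`` is non-empty; warnings alone never block output.
    """

    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    def error(self, code: str, location: str, row: int | None, message: str) -> None:
        self.errors.append(Finding(location, row, code, message))

    def warning(self, code: str, location: str, row: int | None, message: str) -> None:
        self.warnings.append(Finding(location, row, code, message))

    def merge(self, other: "ValidationReport") -> "ValidationReport":
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)
        return self

    @property
    def ok(self) -> bool:
        """True when no critical error blocks output."""
        return not self.errors

    def promote_warnings(self) -> None:
        """Strict mode: treat every warning as a critical error."""
        self.errors.extend(self.warnings)
        self.warnings = []

    def sorted_errors(self) -> list[Finding]:
        return sorted(self.errors, key=_sort_key)

    def sorted_warnings(self) -> list[Finding]:
        return sorted(self.warnings, key=_sort_key)
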