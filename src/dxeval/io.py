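"""Spreadsheet input, column validation and tabular output.

Datasets arrive as .xlsx workbooks whose first row is the header.  Cells
are kept raw on read (numbers, text, or the missing sentinel ``None``);
interpretation happens in :func:`validate_and_clean`, which mirrors the
validation a careful analyst applies before computing accuracy metrics:

* rows with a missing value in either selected column are dropped first
  (missingness in unselected columns is irrelevant);
* a qualitative test column and the reference column must contain only
  0/1 (values stored as text or as floats 0.0/1.0 are accepted; anything
  else, e.g. 0.5 or "yes", is rejected);
* a quantitative test column must be numeric, where numeric includes
  number-like text — spreadsheets routinely store numbers as text;
* the reference must retain both levels after cleaning.

Each violation raises :class:`ValidationError` carrying a fixed,
user-facing message.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from numbers import Real
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import openpyxl

from dxeval.metrics import ConfusionMatrix

__all__ = [
    "RawTable",
    "CleanDataset",
    "InputFormatError",
    "ValidationError",
    "MSG_QUALITATIVE_01",
    "MSG_REFERENCE_01",
    "MSG_QUANTITATIVE_NUMERIC",
    "MSG_REFERENCE_BOTH_LEVELS",
    "read_table",
    "validate_and_clean",
    "write_confusion_matrix",
    "write_metrics",
    "write_roc_points",
]

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"

#: fixed workbook timestamp so written files are byte-reproducible
_EPOCH = datetime.datetime(2000, 1, 1)


def _save_workbook(wb: "openpyxl.Workbook", path: Union[str, Path]) -> None:
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    wb.save(Path(path))

MSG_QUALITATIVE_01 = (
    "For qualitative tests, the test variable must contain only 0 and 1 values."
)
MSG_REFERENCE_01 = "The reference variable must contain only 0 and 1 values."
MSG_QUANTITATIVE_NUMERIC = "For quantitative tests, the test variable must be numeric."
MSG_REFERENCE_BOTH_LEVELS = (
    "The reference variable must contain both 0 and 1 after removing missing values."
)


class InputFormatError(ValueError):
    """The input file is not a readable .xlsx workbook (or has no data)."""


class ValidationError(ValueError):
    """A selected column violates one of the dataset validation rules."""


@dataclass
class RawTable:
    """A spreadsheet as read: header names plus raw rows (``None`` = missing)."""

    column_names: list[str]
    rows: list[list[object]]

    def __post_init__(self) -> None:
        if len(set(self.column_names)) != len(self.column_names):
            dupes = sorted(
                {c for c in self.column_names if self.column_names.count(c) > 1}
            )
            raise InputFormatError(
                f"duplicate column names are not allowed: {', '.join(map(str, dupes))}"
            )
        width = len(self.column_names)
        for r in self.rows:
            if len(r) != width:
                raise InputFormatError(
                    f"row width {len(r)} does not match header width {width}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[object]:
        try:
            idx = self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None
        return [r[idx] for r in self.rows]


@dataclass
class CleanDataset:
    """Validated, paired test/reference vectors ready for analysis."""

    test_values: np.ndarray
    ref_values: np.ndarray
    test_kind: str
    n_dropped: int

    def __post_init__(self) -> None:
        self.test_values = np.asarray(self.test_values, dtype=float)
        self.ref_values = np.asarray(self.ref_values, dtype=int)
        if self.test_values.shape != self.ref_values.shape:
            raise ValueError("test and reference vectors must have equal length")

    @property
    def n(self) -> int:
        return int(self.test_values.size)


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, str) and cell.strip() == "":
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    return False


def _as_number(cell: object) -> Optional[float]:
    """Parse a cell to float; number-like text counts. None if unparseable."""
    if isinstance(cell, bool):
        return None
    if isinstance(cell, Real):
        return float(cell)
    if isinstance(cell, str):
        try:
            return float(cell.strip())
        except ValueError:
            return None
    return None


def _is_binary(value: Optional[float]) -> bool:
    return value is not None and value in (0.0, 1.0)


def read_table(path: Union[str, Path], sheet: Union[int, str] = 0) -> RawTable:
    """Read an .xlsx workbook into a :class:`RawTable`.

    The first row is the header; blank cells become ``None``.  Trailing
    fully-empty rows (a common spreadsheet artefact) are trimmed; interior
    blank rows are kept and handled by the missing-value rules downstream.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"input file not found: {path}")
    try:
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:
        raise InputFormatError(
            f"could not read {path} as an .xlsx workbook: {exc}"
        ) from exc
    try:
        if isinstance(sheet, int):
            try:
                ws = wb.worksheets[sheet]
            except IndexError:
                raise InputFormatError(
                    f"workbook {path} has no sheet index {sheet}"
                ) from None
        else:
            if sheet not in wb.sheetnames:
                raise InputFormatError(f"workbook {path} has no sheet named {sheet!r}")
            ws = wb[sheet]
        data = [list(row) for row in ws.iter_rows(values_only=True)]
    finally:
        wb.close()

    while data and all(c is None for c in data[-1]):
        data.pop()
    if not data:
        raise InputFormatError(f"no data rows in {path}")
    header = ["" if c is None else str(c) for c in data[0]]
    rows = data[1:]
    if not rows:
        raise InputFormatError(f"no data rows in {path}")
    return RawTable(column_names=header, rows=rows)


def validate_and_clean(
    table: RawTable,
    test_col: str,
    ref_col: str,
    test_kind: str = QUANTITATIVE,
) -> CleanDataset:
    """Select, clean and validate the test/reference column pair.

    Rows missing either selected cell are dropped first; the validation
    rules then run on what remains.  Violations raise
    :class:`ValidationError` with the corresponding fixed message.
    """
    if test_kind not in (QUALITATIVE, QUANTITATIVE):
        raise ValueError(f"test_kind must be {QUALITATIVE!r} or {QUANTITATIVE!r}")
    if test_col == ref_col:
        raise ValueError("test and reference columns must be distinct")
    test_cells = table.column(test_col)
    ref_cells = table.column(ref_col)

    kept = [
        (t, r)
        for t, r in zip(test_cells, ref_cells)
        if not (_is_missing(t) or _is_missing(r))
    ]
    n_dropped = table.n_rows - len(kept)

    test_parsed = [_as_number(t) for t, _ in kept]
    ref_parsed = [_as_number(r) for _, r in kept]

    if test_kind == QUALITATIVE:
        if not all(_is_binary(v) for v in test_parsed):
            raise ValidationError(MSG_QUALITATIVE_01)
    else:
        if not all(v is not None for v in test_parsed):
            raise ValidationError(MSG_QUANTITATIVE_NUMERIC)
    if not all(_is_binary(v) for v in ref_parsed):
        raise ValidationError(MSG_REFERENCE_01)
    ref_int = [int(v) for v in ref_parsed]
    if not (0 in ref_int and 1 in ref_int):
        raise ValidationError(MSG_REFERENCE_BOTH_LEVELS)

    return CleanDataset(
        test_values=np.array(test_parsed, dtype=float),
        ref_values=np.array(ref_int, dtype=int),
        test_kind=test_kind,
        n_dropped=n_dropped,
    )


def write_confusion_matrix(cm: ConfusionMatrix, path: Union[str, Path]) -> None:
    """Write the 2x2 table plus a labelled count list to a one-sheet workbook.

    Rows are test positive/negative, columns disease present/absent; zeros
    are written as numeric 0, never blank.
    """
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Confusion matrix"
    ws.append(["", "Disease present", "Disease absent"])
    ws.append(["Test positive", cm.tp, cm.fp])
    ws.append(["Test negative", cm.fn, cm.tn])
    ws.append([None, None, None])
    ws.append(["Count", "Value", None])
    for label, value in cm.as_counts().items():
        ws.append([label, value, None])
    _save_workbook(wb, path)


def write_metrics(report, path: Union[str, Path]) -> None:
    """Write a metrics report as one row per indicator.

    Columns are metric, estimate, ci_lower, ci_upper; values are rendered
    with the display-rounding rule (3 decimals, half-up) and missing
    entries as the text "NA".
    """
    from dxeval.reporting import round_for_display

    decimals = report.config.report_decimals if report.config is not None else 3
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Metrics"
    ws.append(["metric", "estimate", "ci_lower", "ci_upper"])
    for est in report:
        ws.append(
            [
                est.label,
                round_for_display(est.value, decimals),
                round_for_display(est.lower, decimals),
                round_for_display(est.upper, decimals),
            ]
        )
    _save_workbook(wb, path)


def write_roc_points(curve, path: Union[str, Path]) -> None:
    """Write ROC coordinates as UTF-8 CSV (threshold, sensitivity, specificity).

    Infinite sentinel thresholds are serialized as "-Inf"/"Inf".
    """

    def _fmt_threshold(t: float) -> str:
        if t == float("inf"):
            return "Inf"
        if t == float("-inf"):
            return "-Inf"
        return repr(t)

    lines = ["threshold,sensitivity,specificity"]
    for p in curve.points:
        lines.append(f"{_fmt_threshold(p.threshold)},{p.se!r},{p.sp!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
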