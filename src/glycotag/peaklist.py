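"""Peak-list input: instrument export dialect and workbook extraction.

Peak-list files follow the common MALDI-TOF export layout: three header
rows, then one data row per peak with m/z in column 1 and peak area in
column 7.  The analysis metadata lives in the second header row
(spreadsheet cells A2-E2):

====  =======================================================
cell  meaning
====  =======================================================
A2    quantity of internal standard (pmol)
B2    error tolerance for precursor m/z (Da)
C2    total protein analysed (ug)
D2    series number (integer >= 1) identifying the group
E2    short series name (e.g. ``wt(-)``)
====  =======================================================

Files may be tab- or comma-delimited (sniffed per file).  Multi-tab
workbooks (one measurement per tab) are split into per-experiment
delimited text files by :func:`extract_workbook`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

#: column indices (0-based) in data rows
MZ_COLUMN = 0
AREA_COLUMN = 6
N_HEADER_ROWS = 3

_META_CELLS = ("A2", "B2", "C2", "D2", "E2")


class PeakListError(ValueError):
    """Malformed peak-list file."""


@dataclass(frozen=True)
class Peak:
    mz: float
    area: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise PeakListError(f"non-positive m/z {self.mz}")
        if self.area < 0:
            raise PeakListError(f"negative area {self.area}")


@dataclass(frozen=True)
class ExperimentMeta:
    """User-entered metadata from header row 2."""

    internal_standard_pmol: float
    tolerance: float
    protein_ug: float
    group_id: int
    group_name: str

    def __post_init__(self) -> None:
        if self.internal_standard_pmol <= 0:
            raise PeakListError("internal standard quantity (A2) must be > 0")
        if self.tolerance <= 0:
            raise PeakListError("error tolerance (B2) must be > 0")
        if self.protein_ug <= 0:
            raise PeakListError("protein quantity (C2) must be > 0")
        if self.group_id < 1:
            raise PeakListError("series number (D2) must be >= 1")


@dataclass
class Experiment:
    """One MS measurement: metadata plus peaks sorted by m/z."""

    meta: ExperimentMeta
    peaks: list[Peak]
    name: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)


def _sniff_delimiter(sample: str) -> str:
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def _parse_meta(cells: list[str], source: str) -> ExperimentMeta:
    values = []
    for idx, cell_name in enumerate(_META_CELLS):
        if idx >= len(cells) or not cells[idx].strip():
            raise PeakListError(f"{source}: missing metadata cell {cell_name}")
        values.append(cells[idx].strip())
    try:
        is_pmol = float(values[0])
    except ValueError:
        raise PeakListError(f"{source}: cell A2 is not a number: {values[0]!r}")
    try:
        tol = float(values[1])
    except ValueError:
        raise PeakListError(f"{source}: cell B2 is not a number: {values[1]!r}")
    try:
        protein = float(values[2])
    except ValueError:
        raise PeakListError(f"{source}: cell C2 is not a number: {values[2]!r}")
    try:
        group = int(values[3])
    except ValueError:
        raise PeakListError(f"{source}: cell D2 is not an integer: {values[3]!r}")
    return ExperimentMeta(internal_standard_pmol=is_pmol, tolerance=tol,
                          protein_ug=protein, group_id=group,
                          group_name=values[4])


def read_peaklist(path: str | Path) -> Experiment:
    """Read one peak-list export into an :class:`Experiment`."""
    path = Path(path)
    text = path.read_text()
    rows = [line for line in text.splitlines()]
    while rows and not rows[-1].strip():
        rows.pop()
    if len(rows) < N_HEADER_ROWS + 1:
        raise PeakListError(
            f"{path}: need {N_HEADER_ROWS} header rows and at least one "
            f"data row, found {len(rows)} lines")
    delim = _sniff_delimiter("\n".join(rows[:N_HEADER_ROWS + 1]))
    cells = [row.split(delim) for row in rows]
    meta = _parse_meta(cells[1], str(path))
    peaks = []
    for lineno, row in enumerate(cells[N_HEADER_ROWS:], start=N_HEADER_ROWS + 1):
        if not any(c.strip() for c in row):
            continue
        if len(row) <= AREA_COLUMN:
            raise PeakListError(
                f"{path}:{lineno}: data row has {len(row)} columns; peak "
                f"area expected in column {AREA_COLUMN + 1}")
        try:
            mz = float(row[MZ_COLUMN])
        except ValueError:
            raise PeakListError(
                f"{path}:{lineno}: non-numeric m/z {row[MZ_COLUMN]!r}")
        try:
            area = float(row[AREA_COLUMN])
        except ValueError:
            raise PeakListError(
                f"{path}:{lineno}: non-numeric area {row[AREA_COLUMN]!r}")
        peaks.append(Peak(mz=mz, area=area))
    return Experiment(meta=meta, peaks=peaks, name=path.stem)


def write_peaklist(experiment: Experiment, path: str | Path,
                   delimiter: str = ",") -> None:
    """Write an experiment back to the three-header-row dialect."""
    meta = experiment.meta
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["m/z", "meta", "", "", "", "", "area"])
        writer.writerow([meta.internal_standard_pmol, meta.tolerance,
                         meta.protein_ug, meta.group_id, meta.group_name])
        writer.writerow([])
        for peak in experiment.peaks:
            row = [f"{peak.mz:.6f}"] + [""] * (AREA_COLUMN - 1) + [f"{peak.area:.6f}"]
            writer.writerow(row)


def extract_workbook(path: str | Path, out_dir: str | Path) -> list[Path]:
    """Split a multi-tab workbook into one CSV per tab (named after the tab).

    Cell contents are passed through unmodified; one output file per sheet.
    """
    from openpyxl import load_workbook

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    book = load_workbook(path, read_only=True, data_only=True)
    if not book.sheetnames:
        raise PeakListError(f"{path}: workbook has no sheets")
    written = []
    for sheet_name in book.sheetnames:
        sheet = book[sheet_name]
        out_path = out_dir / f"{sheet_name}.csv"
        n_rows = 0
        with open(out_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in sheet.iter_rows(values_only=True):
                writer.writerow(["" if v is None else v for v in row])
                n_rows += 1
        if n_rows <= N_HEADER_ROWS:
            warnings.warn(
                f"sheet {sheet_name!r} has no data rows", stacklevel=2)
        written.append(out_path)
    book.close()
    return written
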