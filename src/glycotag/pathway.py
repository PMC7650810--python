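"""Biosynthetic pathway maps: CSV dialect, expression binding, HTML render.

A pathway map is a spreadsheet-like CSV grid.  A glycan occupies a
vertical block of four cells in one column:

    row r   : glycan class label   (e.g. "N-glycans on folded proteins")
    row r+1 : type label           (e.g. "HM")
    row r+2 : core-qualified five-digit notation (e.g. "C:30000")
    row r+3 : localization keyword (ER / Golgi / cytoplasm / lysosome)

The notation cell identifies the block; any cell whose text is an arrow
token (``ra.png``, ``la.png``, ``ua.png``, ``da.png`` — right/left/up/down)
is a connector and is rendered as an inline glyph, so user maps written
for the original image-based convention load unchanged.  Localization
sets the cell background: yellow = ER, pale blue = Golgi, gray =
cytoplasm, magenta = lysosome.

Expression statistics bind to cells by (core, notation); compositions
shared by several structural types are summed and flagged composite.
Cells absent from the expression table keep a "not measured" marker —
binding never fails.
"""

from __future__ import annotations

import csv
import html
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .composition import GlycanComposition, NotationError, parse_composition
from .expression import ExpressionTable

LOCALIZATION_COLORS = {
    "ER": "#f7e96b",          # yellow
    "Golgi": "#bcd9f2",       # pale blue
    "cytoplasm": "#d4d4d4",   # gray
    "lysosome": "#f2a0e8",    # magenta
}

ARROW_GLYPHS = {
    "ra.png": "&#8594;", "la.png": "&#8592;",
    "ua.png": "&#8593;", "da.png": "&#8595;",
}

_NOTATION_CELL = re.compile(r"^(C|N1|N2):\S*$")


class PathwayFormatError(ValueError):
    pass


def _cell_name(col: int, row: int) -> str:
    """Spreadsheet-style coordinate, e.g. column 70, row 40 -> ``BS41``."""
    letters = ""
    c = col + 1
    while c:
        c, rem = divmod(c - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return f"{letters}{row + 1}"


@dataclass
class GlycanCell:
    col: int
    row: int                      # grid row of the notation cell
    class_label: str
    type_label: str
    composition: GlycanComposition
    localization: str

    @property
    def coordinate(self) -> str:
        return _cell_name(self.col, self.row)


@dataclass
class PathwayMap:
    grid: list[list[str]]
    cells: list[GlycanCell]
    arrows: list[tuple[int, int, str]]      # (col, row, token)

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_cols(self) -> int:
        return max((len(r) for r in self.grid), default=0)


def read_pathway_map(path: str | Path) -> PathwayMap:
    with open(path, newline="") as fh:
        grid = [[c.strip() for c in row] for row in csv.reader(fh)]
    cells, arrows = [], []
    for r, row in enumerate(grid):
        for c, value in enumerate(row):
            if not value:
                continue
            if value in ARROW_GLYPHS:
                arrows.append((c, r, value))
                continue
            if _looks_like_notation(value):
                if r == 0 or r + 1 >= len(grid):
                    raise PathwayFormatError(
                        f"notation cell {_cell_name(c, r)} has no room for "
                        f"its 4-cell block")
                try:
                    comp = parse_composition(value)
                except NotationError as exc:
                    raise PathwayFormatError(
                        f"cell {_cell_name(c, r)}: {exc}") from None
                class_label = grid[r - 2][c] if r >= 2 and c < len(grid[r - 2]) else ""
                type_label = grid[r - 1][c] if c < len(grid[r - 1]) else ""
                loc_row = grid[r + 1]
                localization = loc_row[c] if c < len(loc_row) else ""
                loc_key = _localization_key(localization)
                if loc_key is None:
                    raise PathwayFormatError(
                        f"cell {_cell_name(c, r + 1)}: unknown localization "
                        f"{localization!r}")
                cells.append(GlycanCell(
                    col=c, row=r, class_label=class_label,
                    type_label=type_label, composition=comp,
                    localization=loc_key))
    return PathwayMap(grid=grid, cells=cells, arrows=arrows)


def _looks_like_notation(value: str) -> bool:
    return bool(_NOTATION_CELL.match(value))


def _localization_key(text: str) -> str | None:
    lowered = text.lower()
    for key in LOCALIZATION_COLORS:
        if re.search(rf"\b{key.lower()}\b", lowered):
            return key
    return None


def default_pathway_map() -> PathwayMap:
    """The bundled fused N-glycan + FNG pathway map (illustrative)."""
    ref = resources.files("glycotag.data").joinpath("pathway_map.csv")
    with resources.as_file(ref) as path:
        return read_pathway_map(path)


# ---------------------------------------------------------------------------
# binding


@dataclass
class CellPayload:
    measured: bool = False
    composite: bool = False
    series: list[str] = field(default_factory=list)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float | None] = field(default_factory=dict)
    diff: float | None = None           # mean_b - mean_a
    ratio: float | None = None          # mean_b / mean_a (blank if mean_a = 0)
    p: float | None = None


@dataclass
class BoundPathway:
    pathway: PathwayMap
    table: ExpressionTable
    pair: tuple[str, str]
    payloads: dict[tuple[int, int], CellPayload]

    def payload(self, cell: GlycanCell) -> CellPayload:
        return self.payloads[(cell.col, cell.row)]


def bind_expression(pathway: PathwayMap, table: ExpressionTable,
                    pair: tuple[str, str]) -> BoundPathway:
    """Attach per-series statistics to every map cell (idempotent).

    ``pair`` = (series A, series B); diff = mean_B - mean_A and the p-value
    comes from that pair's t-test.  Unmatched cells keep the "not measured"
    marker.
    """
    names = table.design.series_names
    for name in pair:
        if name not in names:
            raise PathwayFormatError(
                f"series {name!r} not in design {names}")
    by_comp: dict[GlycanComposition, list] = {}
    for row in table.rows:
        by_comp.setdefault(row.record.composition, []).append(row)

    payloads = {}
    sa, sb = pair
    key = (sa, sb) if (sa, sb) in (table.rows[0].tests if table.rows else {}) \
        else (sb, sa)
    for cell in pathway.cells:
        rows = by_comp.get(cell.composition)
        if not rows:
            payloads[(cell.col, cell.row)] = CellPayload(measured=False)
            continue
        payload = CellPayload(measured=True, composite=len(rows) > 1,
                              series=list(names))
        for series in names:
            payload.mean[series] = sum(r.mean[series] for r in rows)
            sds = [r.sd[series] for r in rows]
            payload.sd[series] = (None if any(s is None for s in sds)
                                  else math.hypot(*sds))
        mean_a = payload.mean[sa]
        mean_b = payload.mean[sb]
        payload.diff = mean_b - mean_a
        payload.ratio = (mean_b / mean_a) if mean_a != 0 else None
        if len(rows) == 1:
            test = rows[0].tests.get(key)
            payload.p = None if test is None or math.isnan(test.t) else test.p
        else:
            # composite cell: test the summed quantities across replicates
            payload.p = _composite_p(rows, table, sa, sb)
        payloads[(cell.col, cell.row)] = payload
    return BoundPathway(pathway=pathway, table=table, pair=pair,
                        payloads=payloads)


def _composite_p(rows, table: ExpressionTable, sa: str, sb: str):
    from .expression import students_t

    members = {table.design.groups[g]: mem
               for g, mem in table.design.members.items()}
    va = [sum(r.quantities[m] for r in rows) for m in members[sa]]
    vb = [sum(r.quantities[m] for r in rows) for m in members[sb]]
    result = students_t(va, vb, welch=table.welch)
    return None if math.isnan(result.t) else result.p


# ---------------------------------------------------------------------------
# rendering


def render_pathway_html(bound: BoundPathway, mode: str, path: str | Path,
                        threshold: float = 0.05) -> None:
    """Self-contained HTML rendering of a bound pathway.

    ``mode="bars"`` draws one bar per series in every measured cell (series
    order follows the design); ``mode="values"`` prints diff, ratio and p,
    coloring the cell text red for a significant increase and blue for a
    significant decrease — strictly ``p < threshold`` and a non-zero diff.
    """
    if mode not in ("bars", "values"):
        raise ValueError(f"mode must be 'bars' or 'values', got {mode!r}")
    pathway = bound.pathway
    blocks = {}
    for cell in pathway.cells:
        blocks[(cell.col, cell.row)] = cell

    max_mean = max((max(p.mean.values()) for p in bound.payloads.values()
                    if p.measured and p.mean), default=0.0)

    covered = {(c.col, c.row + dr) for c in pathway.cells
               for dr in (-2, -1, 0, 1)}
    arrow_at = {(c, r): token for c, r, token in pathway.arrows}

    rows_html = []
    for r in range(pathway.n_rows):
        cells_html = []
        for c in range(pathway.n_cols):
            cell = blocks.get((c, r))
            if cell is not None:
                cells_html.append(_render_block(
                    cell, bound.payload(cell), bound.pair, mode, threshold,
                    max_mean))
            elif (c, r) in arrow_at:
                cells_html.append(
                    f'<td class="arrow">{ARROW_GLYPHS[arrow_at[(c, r)]]}</td>')
            elif (c, r) in covered:
                continue  # consumed by a glycan block
            else:
                text = pathway.grid[r][c] if c < len(pathway.grid[r]) else ""
                cells_html.append(f"<td>{html.escape(text)}</td>")
        rows_html.append("<tr>" + "".join(cells_html) + "</tr>")

    title = (f"Pathway — {bound.pair[1]} vs {bound.pair[0]} ({mode})")
    document = _PAGE_TEMPLATE.format(title=html.escape(title),
                                     body="\n".join(rows_html))
    Path(path).write_text(document)


def _render_block(cell: GlycanCell, payload: CellPayload, pair, mode,
                  threshold, max_mean) -> str:
    color = LOCALIZATION_COLORS[cell.localization]
    head = (f"<div class='lbl'>{html.escape(cell.class_label)}</div>"
            f"<div class='lbl'>{html.escape(cell.type_label)}</div>"
            f"<div class='not'>{html.escape(str(cell.composition))}"
            f"{' *' if payload.composite else ''}</div>")
    if not payload.measured:
        body = "<div class='nm'>not measured</div>"
        style = ""
    elif mode == "bars":
        bars = []
        for series in payload.series:
            mean = payload.mean[series]
            height = 0 if max_mean == 0 else max(1, round(40 * mean / max_mean))
            bars.append(
                f"<div class='bar' title='{html.escape(series)}: {mean:.3g}'"
                f" style='height:{height}px'></div>")
        body = "<div class='bars'>" + "".join(bars) + "</div>"
        style = ""
    else:
        significant = (payload.p is not None and payload.p < threshold
                       and payload.diff not in (None, 0.0))
        css = ""
        if significant and payload.diff > 0:
            css = "color:#c00000;font-weight:bold"
        elif significant and payload.diff < 0:
            css = "color:#0000c0;font-weight:bold"
        ratio = "" if payload.ratio is None else f"{payload.ratio:.3g}"
        p_text = "" if payload.p is None else f"{payload.p:.3g}"
        body = (f"<div style='{css}'>diff {payload.diff:+.3g}<br>"
                f"ratio {ratio}<br>p {p_text}</div>")
        style = ""
    return (f"<td rowspan='4' class='glycan' style='background:{color};{style}'>"
            f"{head}{body}</td>")


_PAGE_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; font-size: 11px; }}
table {{ border-collapse: collapse; }}
td {{ padding: 2px 4px; vertical-align: middle; }}
td.glycan {{ border: 1px solid #888; min-width: 90px; }}
td.arrow {{ font-size: 18px; text-align: center; }}
.lbl {{ color: #333; }}
.not {{ font-weight: bold; }}
.nm {{ color: #999; font-style: italic; }}
.bars {{ display: flex; align-items: flex-end; gap: 3px; height: 42px; }}
.bar {{ width: 12px; background: #4472c4; }}
.bars .bar:nth-child(2) {{ background: #ed7d31; }}
.bars .bar:nth-child(3) {{ background: #70ad47; }}
</style></head>
<body><h2>{title}</h2>
<table>
{body}
</table></body></html>
"""
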