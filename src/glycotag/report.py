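"""Self-contained HTML reports: per-glycan bar charts and the calibration plot.

No external assets or JavaScript: bars are CSS boxes and the calibration
scatter is inline SVG, so the files open in any browser.
"""

from __future__ import annotations

import html
from pathlib import Path

from .annotate import CalibrationModel, CandidateSet
from .expression import ExpressionTable

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; font-size: 12px; }}
.chart {{ display: inline-block; border: 1px solid #ccc; margin: 6px;
          padding: 6px; vertical-align: top; }}
.chart h4 {{ margin: 0 0 4px 0; font-size: 12px; }}
.plot {{ display: flex; align-items: flex-end; gap: 10px; height: 110px; }}
.group {{ display: flex; flex-direction: column; align-items: center; }}
.bar {{ width: 22px; background: #4472c4; position: relative; }}
.err {{ position: absolute; left: 50%; width: 1px; background: #222; }}
.lab {{ font-size: 10px; margin-top: 2px; }}
</style></head><body>
<h2>{title}</h2>
{body}
</body></html>
"""


def render_quant_html(table: ExpressionTable, path: str | Path,
                      max_charts: int | None = None) -> None:
    """One bar chart per (detected) glycan: one bar per series, error bars
    showing the sample standard deviation, m/z and composition in the
    header."""
    names = table.design.series_names
    charts = []
    rows = [r for r in table.rows if any(v > 0 for v in r.mean.values())]
    if max_charts is not None:
        rows = rows[:max_charts]
    for row in rows:
        peak = max((row.mean[s] + (row.sd[s] or 0.0)) for s in names) or 1.0
        groups = []
        for s in names:
            mean = row.mean[s]
            sd = row.sd[s]
            h = max(1, round(100 * mean / peak)) if mean > 0 else 0
            err = ""
            if sd:
                eh = round(100 * 2 * sd / peak)
                top = round(100 * (mean + sd) / peak)
                err = (f"<div class='err' style='height:{eh}px;"
                       f"bottom:{h - top + eh}px'></div>")
            groups.append(
                f"<div class='group'><div class='bar' style='height:{h}px'"
                f" title='{mean:.4g} &plusmn; {sd if sd is not None else 0:.2g}'>"
                f"{err}</div><div class='lab'>{html.escape(s)}</div></div>")
        charts.append(
            f"<div class='chart'><h4>m/z {row.record.mz:.4f} &mdash; "
            f"{html.escape(str(row.record.composition))} "
            f"({html.escape(row.record.type_code)})</h4>"
            f"<div class='plot'>{''.join(groups)}</div></div>")
    Path(path).write_text(_PAGE.format(
        title="Per-glycan quantities (pmol / 100 &micro;g protein)",
        body="\n".join(charts)))


def render_calib_html(model: CalibrationModel, candidates: CandidateSet,
                      path: str | Path) -> None:
    """Deviation-versus-m/z scatter with the cluster and fitted drift line."""
    matches = candidates.matches
    width, height, pad = 640, 420, 45
    if matches:
        mzs = [m.record.mz for m in matches]
        devs = [m.deviation for m in matches]
        x0, x1 = min(mzs), max(mzs)
        y0, y1 = min(devs), max(devs)
    else:
        x0, x1, y0, y1 = 0.0, 1.0, -1.0, 1.0
    if x1 == x0:
        x1 = x0 + 1.0
    if y1 == y0:
        y0, y1 = y0 - 0.01, y1 + 0.01
    ypad = 0.1 * (y1 - y0)
    y0, y1 = y0 - ypad, y1 + ypad

    def sx(x):
        return pad + (x - x0) / (x1 - x0) * (width - 2 * pad)

    def sy(y):
        return height - pad - (y - y0) / (y1 - y0) * (height - 2 * pad)

    cluster = set(zip(model.cluster_mz, model.cluster_deviation))
    points = []
    for m in matches:
        in_cluster = (round(m.record.mz, 6), round(m.deviation, 6)) in cluster
        accepted = abs(model.residual(m)) <= model.acceptance
        color = "#d08000" if in_cluster else ("#888" if accepted else "#c02020")
        points.append(
            f"<circle cx='{sx(m.record.mz):.1f}' cy='{sy(m.deviation):.1f}' "
            f"r='3' fill='{color}' fill-opacity='0.8'/>")
    line = ""
    if not model.is_identity:
        line = (f"<line x1='{sx(x0):.1f}' y1='{sy(model.predict(x0)):.1f}' "
                f"x2='{sx(x1):.1f}' y2='{sy(model.predict(x1)):.1f}' "
                f"stroke='#2040c0' stroke-width='1.5'/>")
    axes = (
        f"<line x1='{pad}' y1='{height - pad}' x2='{width - pad}' "
        f"y2='{height - pad}' stroke='#000'/>"
        f"<line x1='{pad}' y1='{pad}' x2='{pad}' y2='{height - pad}' "
        f"stroke='#000'/>"
        f"<text x='{width / 2}' y='{height - 8}' text-anchor='middle' "
        f"font-size='12'>m/z (theoretical)</text>"
        f"<text x='12' y='{height / 2}' font-size='12' "
        f"transform='rotate(-90 12 {height / 2})' text-anchor='middle'>"
        f"deviation (Da)</text>")
    ticks = []
    for frac in (0.0, 0.5, 1.0):
        xv = x0 + frac * (x1 - x0)
        yv = y0 + frac * (y1 - y0)
        ticks.append(f"<text x='{sx(xv):.0f}' y='{height - pad + 14}' "
                     f"text-anchor='middle' font-size='10'>{xv:.0f}</text>")
        ticks.append(f"<text x='{pad - 4}' y='{sy(yv):.0f}' "
                     f"text-anchor='end' font-size='10'>{yv:.3f}</text>")
    caption = ("identity model (no calibration)" if model.is_identity else
               f"&delta; = {model.intercept:.4g} + {model.slope:.3g} &middot; m/z; "
               f"acceptance &plusmn;{model.acceptance:.4g} Da; "
               f"cluster n = {model.n_cluster}; standards confirmed: "
               f"{'yes' if model.standards_confirmed else 'no'}")
    svg = (f"<svg width='{width}' height='{height}' "
           f"xmlns='http://www.w3.org/2000/svg'>{axes}{''.join(ticks)}"
           f"{line}{''.join(points)}</svg>")
    body = (f"{svg}<p>{caption}</p>"
            "<p>orange: maximum cluster &middot; gray: annotated within the "
            "acceptance distance &middot; red: rejected (contaminants)</p>")
    Path(path).write_text(_PAGE.format(title="Mass-drift calibration", body=body))
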