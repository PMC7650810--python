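"""Expression tables: per-series statistics and result files.

Given per-experiment annotation results grouped into named series
(condition groups), this module assembles the glycan x experiment quantity
matrix, computes per-series mean, sample standard deviation and
coefficient of variation, and performs a two-sample Student's t-test
(pooled variance; Welch's correction optional) for every pair of series.

Raw p-values are reported without multiple-testing correction, matching
the downstream pathway-highlighting convention (p < 0.05); treat them
accordingly when many glycans are screened.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats as _stats

from .annotate import AnnotationResult, count_unique_mz
from .composition import parse_composition
from .listing import GlycanRecord, MZ_DECIMALS


class DesignError(ValueError):
    """Inconsistent series design."""


@dataclass(frozen=True)
class TTestResult:
    series_a: str
    series_b: str
    t: float
    p: float
    df: float


@dataclass
class SeriesDesign:
    """Mapping of experiments to named series (condition groups)."""

    groups: dict[int, str]                  # group_id -> name
    members: dict[int, list[str]]           # group_id -> experiment names

    @classmethod
    def from_results(cls, results: list[AnnotationResult]) -> "SeriesDesign":
        groups: dict[int, str] = {}
        members: dict[int, list[str]] = {}
        for res in results:
            gid, name = res.meta.group_id, res.meta.group_name
            if gid in groups and groups[gid] != name:
                raise DesignError(
                    f"series {gid} named both {groups[gid]!r} and {name!r}")
            groups.setdefault(gid, name)
            members.setdefault(gid, []).append(res.name)
        if not groups:
            raise DesignError("no experiments")
        return cls(groups=groups, members=members)

    @property
    def series_names(self) -> list[str]:
        return [self.groups[g] for g in sorted(self.groups)]


def students_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> TTestResult:
    """Two-sample two-tailed t-test.

    Pooled-variance Student's t by default (df = n1 + n2 - 2); Welch's
    unequal-variance form when ``welch`` is set.  Identical samples give
    t = 0, p = 1 (including the all-zero case common for undetected
    glycans).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return TTestResult("", "", math.nan, math.nan, math.nan)
    diff = a.mean() - b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return TTestResult("", "",
                               0.0 if diff == 0 else math.inf * np.sign(diff),
                               1.0 if diff == 0 else 0.0, n1 + n2 - 2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
        if se2 == 0:
            return TTestResult("", "", 0.0 if diff == 0 else math.inf * np.sign(diff),
                               1.0 if diff == 0 else 0.0, df)
    t = diff / math.sqrt(se2)
    p = 2.0 * _stats.t.sf(abs(t), df)
    return TTestResult("", "", float(t), float(p), float(df))


@dataclass
class GlycanStats:
    """Per-glycan statistics across the whole design."""

    record: GlycanRecord
    quantities: dict[str, float]            # experiment name -> quantity
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float | None] = field(default_factory=dict)
    cv: dict[str, float | None] = field(default_factory=dict)
    tests: dict[tuple[str, str], TTestResult] = field(default_factory=dict)


@dataclass
class ExpressionTable:
    design: SeriesDesign
    experiments: list[str]
    rows: list[GlycanStats]
    welch: bool = False

    @property
    def series_pairs(self) -> list[tuple[str, str]]:
        names = self.design.series_names
        return list(combinations(names, 2))

    def row_for(self, composition_text: str) -> list[GlycanStats]:
        comp = parse_composition(composition_text)
        return [r for r in self.rows if r.record.composition == comp]


def aggregate_stats(results: list[AnnotationResult],
                    design: SeriesDesign | None = None,
                    welch: bool = False) -> ExpressionTable:
    """Build the expression table from per-experiment annotation results.

    The internal standard is a spike-in, not an analyte, and never appears
    in the table.  Series with a single experiment get blank S.D./C.V. and
    are excluded from t-tests (with a warning).
    """
    if not results:
        raise DesignError("no annotation results")
    design = design or SeriesDesign.from_results(results)
    names = [res.name for res in results]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate experiment names in {names}")

    singletons = [design.groups[g] for g, mem in design.members.items()
                  if len(mem) < 2]
    if singletons:
        warnings.warn(
            f"series with a single experiment: {singletons}; S.D., C.V. "
            f"and t-tests are undefined for them", stacklevel=2)

    # all lists in the run must agree on the record set
    record_keys = [tuple(a.record.key() for a in res.annotations)
                   for res in results]
    if len(set(record_keys)) != 1:
        raise DesignError("experiments were annotated against different lists")

    by_series: dict[str, list[str]] = {
        design.groups[g]: mem for g, mem in design.members.items()}

    rows = []
    n_records = len(results[0].annotations)
    for idx in range(n_records):
        record = results[0].annotations[idx].record
        quantities = {res.name: res.annotations[idx].quantity
                      for res in results}
        row = GlycanStats(record=record, quantities=quantities)
        for series, mem in by_series.items():
            values = np.array([quantities[m] for m in mem], dtype=float)
            row.mean[series] = float(values.mean())
            if len(values) >= 2:
                sd = float(values.std(ddof=1))
                row.sd[series] = sd
                row.cv[series] = sd / row.mean[series] if row.mean[series] != 0 else None
            else:
                row.sd[series] = None
                row.cv[series] = None
        for pair in combinations(design.series_names, 2):
            sa, sb = pair
            va = np.array([quantities[m] for m in by_series[sa]], dtype=float)
            vb = np.array([quantities[m] for m in by_series[sb]], dtype=float)
            res_t = students_t(va, vb, welch=welch)
            row.tests[pair] = TTestResult(sa, sb, res_t.t, res_t.p, res_t.df)
        rows.append(row)
    return ExpressionTable(design=design,
                           experiments=names, rows=rows, welch=welch)


# ---------------------------------------------------------------------------
# result files


def _fmt(value, decimals=None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if decimals is not None:
        return f"{value:.{decimals}f}"
    return repr(float(value))


def write_out_list(result: AnnotationResult, path: str | Path) -> None:
    """Per-experiment annotation file (``out_list.csv`` layout).

    Columns: composition, five-digit notation, type, theoretical m/z,
    deviation (observed - theoretical), area, pmol per 100 ug protein.
    Undetected glycans are rows of zeros.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["composition", "five_digit", "type",
                         "mz_theoretical", "deviation", "area",
                         "pmol_per_100ug"])
        for a in result.annotations:
            comp = a.record.composition
            writer.writerow([
                str(comp),
                str(comp).split(":", 1)[1],
                a.record.type_code,
                f"{a.record.mz:.{MZ_DECIMALS}f}",
                _fmt(a.deviation) if a.accepted else "0",
                _fmt(a.area) if a.accepted else "0",
                _fmt(a.quantity) if a.accepted else "0",
            ])


def read_out_list(path: str | Path) -> list[dict]:
    """Read an out_list file back; quantities round-trip bit-exactly."""
    with open(path, newline="") as fh:
        return [
            {**row,
             "mz_theoretical": float(row["mz_theoretical"]),
             "deviation": float(row["deviation"] or "nan"),
             "area": float(row["area"]),
             "pmol_per_100ug": float(row["pmol_per_100ug"])}
            for row in csv.DictReader(fh)]


def write_exp_list(table: ExpressionTable, path: str | Path) -> None:
    """Study-level expression summary (``exp_list.csv`` layout).

    One row per glycan: per-experiment quantities, then mean / S.D. / C.V.
    per series, then t and p for every pair of series.  An undefined C.V.
    (zero mean) is an empty cell, not 0.
    """
    names = table.design.series_names
    pairs = table.series_pairs
    series_of = {}
    for gid, members in table.design.members.items():
        for member in members:
            series_of[member] = table.design.groups[gid]
    header = ["composition", "type", "mz_theoretical"]
    header += [f"quantity[{e}@{series_of[e]}]" for e in table.experiments]
    for s in names:
        header += [f"mean[{s}]", f"sd[{s}]", f"cv[{s}]"]
    for a, b in pairs:
        header += [f"t[{a}|{b}]", f"p[{a}|{b}]"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in table.rows:
            cells = [str(row.record.composition), row.record.type_code,
                     f"{row.record.mz:.{MZ_DECIMALS}f}"]
            cells += [_fmt(row.quantities[e]) for e in table.experiments]
            for s in names:
                cells += [_fmt(row.mean[s]), _fmt(row.sd[s]), _fmt(row.cv[s])]
            for pair in pairs:
                test = row.tests[pair]
                cells += [_fmt(test.t), _fmt(test.p)]
            writer.writerow(cells)


def read_exp_list(path: str | Path) -> ExpressionTable:
    """Rebuild an :class:`ExpressionTable` from an exp_list file.

    Statistics are recomputed from the stored per-experiment quantities
    (the columns carry the series assignment), so the reconstructed table
    is self-consistent and bindable to pathway maps.
    """
    from .annotate import Annotation, AnnotationResult, CalibrationModel
    from .peaklist import ExperimentMeta
    from .listing import GlycanRecord

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fieldnames = reader.fieldnames or []
        rows = list(reader)
    qcols = [c for c in fieldnames if c.startswith("quantity[")]
    if not qcols:
        raise DesignError(f"{path}: no quantity columns")
    assignments = []
    for col in qcols:
        inner = col[len("quantity["):-1]
        try:
            name, series = inner.rsplit("@", 1)
        except ValueError:
            raise DesignError(f"{path}: malformed column {col!r}")
        assignments.append((col, name, series))
    welch_flag = False
    series_order = list(dict.fromkeys(s for _, _, s in assignments))
    gid = {s: i + 1 for i, s in enumerate(series_order)}
    results = []
    for col, name, series in assignments:
        annotations = []
        for row in rows:
            comp = parse_composition(row["composition"])
            record = GlycanRecord(composition=comp, type_code=row["type"],
                                  mz=float(row["mz_theoretical"]))
            quantity = float(row[col] or 0.0)
            annotations.append(Annotation(
                record=record, accepted=quantity > 0, quantity=quantity))
        meta = ExperimentMeta(internal_standard_pmol=1.0, tolerance=1.0,
                              protein_ug=100.0, group_id=gid[series],
                              group_name=series)
        results.append(AnnotationResult(meta=meta, name=name,
                                        annotations=annotations,
                                        model=CalibrationModel()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate_stats(results, welch=welch_flag)


def write_cluster_input(table: ExpressionTable, path: str | Path) -> None:
    """Tab-delimited expression matrix in the Cluster 3.0 input layout.

    First row: ``GLYCAN`` then experiment names; following rows: one glycan
    per line, label in column 1 and quantities in the remaining columns.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["GLYCAN"] + table.experiments)
        for row in table.rows:
            writer.writerow([row.record.label]
                            + [_fmt(row.quantities[e])
                               for e in table.experiments])


def total_quantity(result: AnnotationResult) -> float:
    """Sum of quantities over all annotations of one experiment."""
    return float(sum(a.quantity for a in result.annotations))


__all__ = [
    "SeriesDesign", "ExpressionTable", "GlycanStats", "TTestResult",
    "aggregate_stats", "students_t", "write_out_list", "read_out_list",
    "write_exp_list", "write_cluster_input", "total_quantity",
    "count_unique_mz", "DesignError",
]
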