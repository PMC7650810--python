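"""Synthetic peak lists and studies with planted ground truth.

The simulator emulates the shape of a MALDI-TOF glycomics study — several
condition series with replicate measurements — so the whole pipeline is
testable without instrument data.  For every planted glycan it places a
peak at the theoretical m/z shifted by a linear mass drift plus truncated
Gaussian jitter; peak areas are proportional to the planted quantity
relative to the internal standard, with multiplicative lognormal noise
(instrument CVs are relative, areas stay positive).  Contaminant peaks are
placed near unplanted list entries but kept a safe margin away from the
drift line with respect to *every* list record within tolerance, so their
rejection is well defined ground truth.

Defaults describe a realistic desk-scale study: tolerance 0.5 Da, drift of
0.05 Da + 2e-6 per Da, sub-mDa residual jitter after internal calibration,
10% relative area noise, three replicates per series.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .listing import GlycanList, GlycanRecord, InternalStandard
from .peaklist import Experiment, ExperimentMeta, Peak, write_peaklist


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DriftSpec:
    intercept: float = 0.05      # Da
    slope: float = 2e-6          # Da per Da

    def at(self, mz: float) -> float:
        return self.intercept + self.slope * mz


@dataclass
class SimulationSpec:
    """Ground truth for a simulated study.

    ``planted`` maps series name -> {record label -> pmol per 100 ug}.
    All planted quantities must be positive; the seed is mandatory.
    """

    glycan_list: GlycanList
    planted: dict[str, dict[str, float]]
    seed: int
    series_ids: dict[str, int] | None = None
    replicates: int = 3
    standard: InternalStandard | None = None
    standard_pmol: float = 10.0
    standard_area: float = 20000.0
    protein_ug: float = 50.0
    tolerance: float = 0.5       # Da
    drift: DriftSpec = field(default_factory=DriftSpec)
    area_sigma: float = 0.1      # lognormal sigma (relative noise)
    mz_jitter_sigma: float = 2e-4   # Da
    mz_jitter_max: float = 4e-3     # truncation; below acceptance floor
    n_contaminants: int = 10
    contaminant_margin: float = 0.02  # min distance from the drift line (Da)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.area_sigma < 0 or self.mz_jitter_sigma < 0:
            raise SimulationError("noise sigmas must be >= 0")
        if self.standard is None:
            if not self.glycan_list.standards:
                raise SimulationError("glycan list carries no internal standard")
            self.standard = self.glycan_list.standards[0]
        for series, quantities in self.planted.items():
            for label, pmol in quantities.items():
                if pmol <= 0:
                    raise SimulationError(
                        f"planted quantity for {label} in {series} must be > 0")
        if self.series_ids is None:
            self.series_ids = {name: i + 1
                               for i, name in enumerate(self.planted)}

    @property
    def records_by_label(self) -> dict[str, GlycanRecord]:
        return {r.label: r for r in self.glycan_list.records}


def _experiment_rng(spec: SimulationSpec, series: str, replicate: int):
    index = list(spec.planted).index(series)
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, index, replicate]))


def simulate_experiment(spec: SimulationSpec, series: str,
                        replicate: int) -> Experiment:
    """One simulated measurement (fully reproducible per seed)."""
    if series not in spec.planted:
        raise SimulationError(f"unknown series {series!r}")
    rng = _experiment_rng(spec, series, replicate)
    records = spec.records_by_label
    quantities = spec.planted[series]
    peaks = []

    def jitter() -> float:
        while True:
            j = rng.normal(0.0, spec.mz_jitter_sigma) if spec.mz_jitter_sigma else 0.0
            if abs(j) <= spec.mz_jitter_max:
                return j

    def area_noise() -> float:
        return math.exp(rng.normal(0.0, spec.area_sigma)) if spec.area_sigma else 1.0

    # internal standard peak
    std = spec.standard
    std_area = spec.standard_area * area_noise()
    peaks.append(Peak(mz=std.mz + spec.drift.at(std.mz) + jitter(),
                      area=std_area))

    # planted glycans: area reproduces the planted pmol/100 ug exactly in
    # the noise-free limit under the quantification formula
    for label, pmol in quantities.items():
        try:
            record = records[label]
        except KeyError:
            raise SimulationError(f"planted glycan {label!r} not in the list")
        area = (pmol * spec.protein_ug / 100.0 / spec.standard_pmol
                * spec.standard_area) * area_noise()
        peaks.append(Peak(mz=record.mz + spec.drift.at(record.mz) + jitter(),
                          area=area))

    # contaminants: near unplanted records, off the drift line
    planted_mz = {round(records[l].mz, 4) for l in quantities}
    planted_mz.add(round(std.mz, 4))
    unplanted = [r for r in spec.glycan_list.records
                 if round(r.mz, 4) not in planted_mz]
    all_mz = np.array(sorted({r.mz for r in spec.glycan_list.records}
                             | {std.mz}))
    for _ in range(spec.n_contaminants):
        for _attempt in range(200):
            host = unplanted[rng.integers(len(unplanted))]
            offset = rng.uniform(0.4, 0.95) * spec.tolerance
            if rng.random() < 0.5:
                offset = -offset
            mz = host.mz + offset
            if _contaminant_ok(mz, all_mz, spec, planted_mz):
                peaks.append(Peak(mz=mz, area=float(rng.uniform(0.05, 0.5))
                                  * spec.standard_area))
                break
        else:
            raise SimulationError(
                "could not place a contaminant away from the drift line "
                "after 200 attempts")

    meta = ExperimentMeta(
        internal_standard_pmol=spec.standard_pmol,
        tolerance=spec.tolerance,
        protein_ug=spec.protein_ug,
        group_id=spec.series_ids[series],
        group_name=series)
    return Experiment(meta=meta, peaks=peaks,
                      name=f"{series}_r{replicate}")


def _contaminant_ok(mz: float, all_mz: np.ndarray, spec: SimulationSpec,
                    planted_mz: set) -> bool:
    lo = np.searchsorted(all_mz, mz - spec.tolerance, side="left")
    hi = np.searchsorted(all_mz, mz + spec.tolerance, side="right")
    for theo in all_mz[lo:hi]:
        if round(float(theo), 4) in planted_mz:
            # never collide with a planted glycan's match window
            return False
        deviation = mz - theo
        if abs(deviation - spec.drift.at(theo)) < spec.contaminant_margin:
            return False
    return True


def simulate_study(spec: SimulationSpec, out_dir: str | Path,
                   workbook: bool = False) -> list[Path]:
    """Write one peak-list file per (series, replicate) plus a manifest.

    With ``workbook=True`` an ``.xlsx`` workbook with one tab per
    measurement is written instead of the per-experiment CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    experiments = [simulate_experiment(spec, series, rep)
                   for series in spec.planted
                   for rep in range(1, spec.replicates + 1)]
    written = []
    if workbook:
        from openpyxl import Workbook

        book = Workbook()
        book.remove(book.active)
        for exp in experiments:
            sheet = book.create_sheet(title=exp.name)
            sheet.append(["m/z", "meta", "", "", "", "", "area"])
            sheet.append([exp.meta.internal_standard_pmol, exp.meta.tolerance,
                          exp.meta.protein_ug, exp.meta.group_id,
                          exp.meta.group_name])
            sheet.append([])
            for peak in exp.peaks:
                sheet.append([peak.mz, "", "", "", "", "", peak.area])
        path = out_dir / "study.xlsx"
        book.save(path)
        written.append(path)
    else:
        for exp in experiments:
            path = out_dir / f"{exp.name}.csv"
            write_peaklist(exp, path)
            written.append(path)
    written.append(write_manifest(spec, out_dir / "ground_truth.csv"))
    return written


def write_manifest(spec: SimulationSpec, path: str | Path) -> Path:
    """Ground-truth manifest: planted quantities and drift parameters."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "series", "label", "value"])
        writer.writerow(["seed", "", "", spec.seed])
        writer.writerow(["drift_intercept", "", "", repr(spec.drift.intercept)])
        writer.writerow(["drift_slope", "", "", repr(spec.drift.slope)])
        writer.writerow(["n_contaminants", "", "", spec.n_contaminants])
        for series, quantities in spec.planted.items():
            for label, pmol in quantities.items():
                writer.writerow(["planted", series, label, repr(pmol)])
    return path


def noise_free(spec: SimulationSpec) -> SimulationSpec:
    """A copy of ``spec`` with all stochastic terms switched off."""
    return replace(spec, area_sigma=0.0, mz_jitter_sigma=0.0)


def pick_planted_records(glist: GlycanList, n: int,
                         seed: int = 0) -> list[GlycanRecord]:
    """``n`` records with distinct m/z spread evenly across the list's range.

    Records sharing an m/z with the internal standard are skipped so planted
    truth never collides with the spike-in.
    """
    std_mz = {round(s.mz, 4) for s in glist.standards}
    by_mz: dict[float, GlycanRecord] = {}
    for record in sorted(glist.records, key=lambda r: r.mz):
        key = round(record.mz, 4)
        if key not in std_mz:
            by_mz.setdefault(key, record)
    unique = list(by_mz.values())
    if len(unique) < n:
        raise SimulationError(
            f"list has only {len(unique)} distinct m/z, cannot plant {n}")
    idx = np.linspace(0, len(unique) - 1, n).round().astype(int)
    return [unique[i] for i in sorted(set(idx.tolist()))]


def build_study_spec(glist: GlycanList, seed: int, series: list[str],
                     replicates: int = 3, n_glycans: int = 20,
                     fold_change: float = 1.0,
                     **overrides) -> SimulationSpec:
    """A ready-made study spec: planted quantities spread over 1-50 pmol/100 ug,
    with every series after the first scaled by ``fold_change``."""
    records = pick_planted_records(glist, n_glycans, seed)
    base = np.geomspace(1.0, 50.0, len(records))
    planted = {}
    for i, name in enumerate(series):
        scale = fold_change ** i if fold_change != 1.0 else 1.0
        planted[name] = {rec.label: float(q * scale)
                         for rec, q in zip(records, base)}
    return SimulationSpec(glycan_list=glist, planted=planted, seed=seed,
                          replicates=replicates, **overrides)
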