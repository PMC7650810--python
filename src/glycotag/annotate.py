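"""Annotation of peak lists against a glycan list, with drift calibration.

The matching proceeds in three stages:

1. *Coarse annotation* — every (glycan record, peak) pair whose m/z
   difference lies within the closed tolerance interval (metadata cell B2,
   in Da) is a candidate; a peak may match several records and vice versa.

2. *Calibration* — observed deviations delta_i = mz_obs - mz_theo drift
   systematically with m/z.  Sliding windows of width tolerance/2 over the
   sorted deviations (including the internal standard's own deviation) are
   ranked by membership count, ties toward the window with the smallest
   median |delta|; the largest window is the "maximum cluster".  For each
   window in turn a line delta = intercept + slope * mz is fitted by least
   squares and refined by trimming members whose residual exceeds the
   acceptance distance (max of 3x the median absolute residual and a
   floor), refitting up to three times; the first window whose fitted line
   passes within the acceptance distance of every matched internal
   standard is adopted.  If no window is validated by the standards,
   annotation falls back to the identity model with a warning.

3. *Refinement* — a candidate is accepted when its deviation lies within
   the acceptance distance of the fitted line; per glycan record the peak
   with the smallest corrected residual wins (ties toward larger area,
   then lower m/z).

Quantities are absolute: peak areas are scaled by the known amount of the
internal standard and normalized per 100 ug protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .listing import GlycanList, GlycanRecord
from .peaklist import Experiment, ExperimentMeta, Peak

#: Lower bound on the acceptance distance (Da); keeps noise-free data from
#: collapsing the band to zero width.
ACCEPTANCE_FLOOR = 0.005
#: Acceptance distance as a multiple of the median absolute residual.
ACCEPTANCE_MAD_FACTOR = 3.0
_REFIT_ITERATIONS = 3


class QuantificationError(RuntimeError):
    """The internal standard was not detected; quantities are undefined."""


@dataclass(frozen=True)
class CandidateMatch:
    record: GlycanRecord
    peak: Peak

    @property
    def deviation(self) -> float:
        return self.peak.mz - self.record.mz


@dataclass
class CandidateSet:
    """Coarse matches for one experiment against one glycan list."""

    experiment: Experiment
    glycan_list: GlycanList
    matches: list[CandidateMatch]
    standard_matches: list[tuple[str, Peak]]   # (standard label, peak)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear mass-drift model delta = intercept + slope * mz."""

    slope: float = 0.0
    intercept: float = 0.0
    acceptance: float = ACCEPTANCE_FLOOR
    n_cluster: int = 0
    standards_confirmed: bool = False
    is_identity: bool = True
    cluster_mz: tuple = ()
    cluster_deviation: tuple = ()

    def predict(self, mz: float) -> float:
        return self.intercept + self.slope * mz

    def residual(self, match: CandidateMatch) -> float:
        return match.deviation - self.predict(match.record.mz)


@dataclass(frozen=True)
class Annotation:
    """Final per-record annotation; undetected records carry quantity 0."""

    record: GlycanRecord
    peak: Peak | None = None
    deviation: float = math.nan
    accepted: bool = False
    area: float = 0.0
    quantity: float = 0.0          # pmol per 100 ug protein


@dataclass
class AnnotationResult:
    meta: ExperimentMeta
    name: str
    annotations: list[Annotation]
    model: CalibrationModel
    standard_label: str = ""
    standard_area: float = 0.0
    quantified: bool = False

    @property
    def accepted(self) -> list[Annotation]:
        return [a for a in self.annotations if a.accepted]


def coarse_annotate(experiment: Experiment, glist: GlycanList) -> CandidateSet:
    """All (record, peak) pairs within the closed tolerance interval."""
    tol = experiment.meta.tolerance
    peaks = experiment.peaks
    mzs = np.array([p.mz for p in peaks]) if peaks else np.empty(0)
    matches = []
    for record in glist.records:
        lo = np.searchsorted(mzs, record.mz - tol, side="left")
        hi = np.searchsorted(mzs, record.mz + tol, side="right")
        for idx in range(lo, hi):
            if abs(peaks[idx].mz - record.mz) <= tol:
                matches.append(CandidateMatch(record=record, peak=peaks[idx]))
    standard_matches = []
    for std in glist.standards:
        lo = np.searchsorted(mzs, std.mz - tol, side="left")
        hi = np.searchsorted(mzs, std.mz + tol, side="right")
        best = None
        for idx in range(lo, hi):
            if abs(peaks[idx].mz - std.mz) <= tol:
                if best is None or (abs(peaks[idx].mz - std.mz)
                                    < abs(best.mz - std.mz)):
                    best = peaks[idx]
        if best is not None:
            standard_matches.append((std.label, best))
    return CandidateSet(experiment=experiment, glycan_list=glist,
                        matches=matches, standard_matches=standard_matches)


def _candidate_windows(deviations: np.ndarray, width: float) -> list[np.ndarray]:
    """Sliding windows of ``width`` over sorted deviations, as boolean
    masks ranked by membership count (ties toward the window whose median
    |delta| is smallest).  The first mask is the "maximum cluster"."""
    order = np.argsort(deviations)
    sorted_dev = deviations[order]
    n = len(sorted_dev)
    ranked: list[tuple[int, float, tuple[int, int]]] = []
    seen: set[tuple[int, int]] = set()
    j = 0
    for i in range(n):
        while j < n and sorted_dev[j] - sorted_dev[i] <= width:
            j += 1
        key = (i, j)
        if key in seen or j - i == 0:
            continue
        seen.add(key)
        med = float(np.median(np.abs(sorted_dev[i:j])))
        ranked.append((-(j - i), med, key))
    ranked.sort()
    masks = []
    for _neg_count, _med, (i, j) in ranked:
        mask = np.zeros(n, dtype=bool)
        mask[order[i:j]] = True
        # drop windows that are subsets of an earlier (larger) one
        if any((mask & ~m).sum() == 0 for m in masks):
            continue
        masks.append(mask)
    return masks


def calibrate(candidates: CandidateSet,
              acceptance_floor: float = ACCEPTANCE_FLOOR) -> CalibrationModel:
    """Fit the mass-drift line on the maximum deviation cluster."""
    matches = candidates.matches
    tol = candidates.experiment.meta.tolerance
    if len(matches) < 2:
        if matches:
            warnings.warn(
                "only one candidate match; falling back to the identity "
                "calibration model", stacklevel=2)
        return CalibrationModel(acceptance=acceptance_floor,
                                n_cluster=len(matches))

    std_deviations = [peak.mz - std.mz
                      for label, peak in candidates.standard_matches
                      for std in candidates.glycan_list.standards
                      if std.label == label]
    std_mzs = [std.mz for label, _peak in candidates.standard_matches
               for std in candidates.glycan_list.standards
               if std.label == label]
    # the spiked standard is itself a glycan signal: its deviation joins
    # the scatter the cluster is selected from
    mz = np.array([m.record.mz for m in matches] + std_mzs)
    dev = np.array([m.deviation for m in matches] + std_deviations)

    # try candidate clusters by decreasing size until one is validated by
    # containing every matched internal standard
    first_fit = None
    for mask in _candidate_windows(dev, tol / 2.0):
        fit = _trimmed_fit(mz, dev, mask, tol, acceptance_floor)
        if fit is None:
            continue
        slope, intercept, acceptance, mask = fit
        confirmed = all(
            abs(d - (intercept + slope * m)) <= acceptance
            for d, m in zip(std_deviations, std_mzs))
        if first_fit is None:
            first_fit = (slope, intercept, acceptance, mask)
        if confirmed:
            return CalibrationModel(
                slope=float(slope), intercept=float(intercept),
                acceptance=float(acceptance), n_cluster=int(mask.sum()),
                standards_confirmed=bool(candidates.standard_matches),
                is_identity=False,
                cluster_mz=tuple(np.round(mz[mask], 6)),
                cluster_deviation=tuple(np.round(dev[mask], 6)))
    if candidates.standard_matches:
        warnings.warn(
            "no deviation cluster contains the internal standard(s); "
            "falling back to the identity model", stacklevel=2)
        return CalibrationModel(acceptance=acceptance_floor,
                                standards_confirmed=False)
    if first_fit is None:
        return CalibrationModel(acceptance=acceptance_floor)
    slope, intercept, acceptance, mask = first_fit
    return CalibrationModel(
        slope=float(slope), intercept=float(intercept),
        acceptance=float(acceptance), n_cluster=int(mask.sum()),
        standards_confirmed=False, is_identity=False,
        cluster_mz=tuple(np.round(mz[mask], 6)),
        cluster_deviation=tuple(np.round(dev[mask], 6)))


def _trimmed_fit(mz, dev, mask, tol, acceptance_floor):
    """Least-squares fit on the cluster with iterative MAD-based trimming."""
    acceptance = acceptance_floor
    slope = intercept = 0.0
    for _ in range(_REFIT_ITERATIONS):
        if mask.sum() < 2:
            return None
        if np.ptp(mz[mask]) == 0:
            slope, intercept = 0.0, float(np.mean(dev[mask]))
        else:
            slope, intercept = np.polyfit(mz[mask], dev[mask], 1)
        residuals = dev - (intercept + slope * mz)
        mad = float(np.median(np.abs(residuals[mask])))
        acceptance = max(ACCEPTANCE_MAD_FACTOR * mad, acceptance_floor)
        new_mask = np.abs(residuals) <= acceptance
        # never grow beyond the original cluster's neighbourhood mid-refit
        new_mask &= np.abs(dev - np.median(dev[mask])) <= tol / 2.0
        if (new_mask == mask).all():
            break
        mask = new_mask
    if mask.sum() < 2:
        return None
    return slope, intercept, acceptance, mask


def refine_annotate(candidates: CandidateSet,
                    model: CalibrationModel) -> AnnotationResult:
    """Accept candidates near the drift line; one peak per glycan record.

    Every record of the list appears exactly once in the result;
    undetected records are present with quantity 0.
    """
    by_record: dict[tuple, CandidateMatch] = {}
    for match in candidates.matches:
        if abs(model.residual(match)) > model.acceptance:
            continue
        key = (match.record.composition, match.record.type_code)
        incumbent = by_record.get(key)
        if incumbent is None or _better(match, incumbent, model):
            by_record[key] = match
    annotations = []
    for record in candidates.glycan_list.records:
        key = (record.composition, record.type_code)
        match = by_record.get(key)
        if match is None:
            annotations.append(Annotation(record=record))
        else:
            annotations.append(Annotation(
                record=record, peak=match.peak, deviation=match.deviation,
                accepted=True, area=match.peak.area))
    return AnnotationResult(
        meta=candidates.experiment.meta, name=candidates.experiment.name,
        annotations=annotations, model=model)


def _better(a: CandidateMatch, b: CandidateMatch,
            model: CalibrationModel) -> bool:
    ra, rb = abs(model.residual(a)), abs(model.residual(b))
    if ra != rb:
        return ra < rb
    if a.peak.area != b.peak.area:
        return a.peak.area > b.peak.area
    return a.peak.mz < b.peak.mz


def quantify(result: AnnotationResult, candidates: CandidateSet) -> AnnotationResult:
    """Absolute quantification against the internal standard.

    quantity = (area / area_IS) * pmol_IS * (100 / protein_ug), in
    pmol per 100 ug protein.  A missing or zero-area standard is a hard
    error: no quantification is possible.
    """
    if not candidates.standard_matches:
        raise QuantificationError(
            f"{result.name}: internal standard not detected within tolerance")
    label, peak = candidates.standard_matches[0]
    if peak.area <= 0:
        raise QuantificationError(
            f"{result.name}: internal standard {label} has zero area")
    meta = result.meta
    scale = meta.internal_standard_pmol * 100.0 / meta.protein_ug / peak.area
    result.annotations = [
        replace(a, quantity=a.area * scale) if a.accepted else a
        for a in result.annotations]
    result.standard_label = label
    result.standard_area = peak.area
    result.quantified = True
    return result


def annotate_experiment(experiment: Experiment, glist: GlycanList,
                        calibration: bool = True) -> AnnotationResult:
    """Full pipeline for one experiment: coarse match, calibrate, refine,
    quantify.  ``calibration=False`` forces the identity drift model."""
    candidates = coarse_annotate(experiment, glist)
    if calibration:
        model = calibrate(candidates)
    else:
        # identity model accepting the full tolerance interval
        model = CalibrationModel(acceptance=experiment.meta.tolerance)
    result = refine_annotate(candidates, model)
    return quantify(result, candidates)


def count_unique_mz(result: AnnotationResult) -> int:
    """Number of distinct theoretical m/z among accepted, quantified records.

    Records sharing one m/z (same composition, different structure) count
    once; the internal standard is not a list record and never counts.
    """
    return len({round(a.record.mz, 4) for a in result.annotations
                if a.accepted and a.quantity > 0})
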