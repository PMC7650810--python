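"""Annotation, calibration and quantification."""

import warnings

import pytest

from glycotag.annotate import (CalibrationModel, QuantificationError,
                               annotate_experiment, calibrate,
                               coarse_annotate, count_unique_mz, quantify,
                               refine_annotate)
from glycotag.peaklist import Experiment, ExperimentMeta, Peak
from glycotag.simulate import (DriftSpec, build_study_spec, noise_free,
                               simulate_experiment)


def _meta(**kw):
    base = dict(internal_standard_pmol=10.0, tolerance=0.5, protein_ug=100.0,
                group_id=1, group_name="wt")
    base.update(kw)
    return ExperimentMeta(**base)


def _exp(peaks, **kw):
    return Experiment(meta=_meta(**kw), peaks=peaks, name="t")


class TestCoarse:
    def test_exact_peak_has_zero_deviation(self, small_list):
        record = small_list.records[0]
        cands = coarse_annotate(_exp([Peak(record.mz, 1.0)]), small_list)
        assert any(m.record == record and m.deviation == 0
                   for m in cands.matches)

    def test_tolerance_interval_is_closed(self, small_list):
        record = small_list.records[0]
        cands = coarse_annotate(_exp([Peak(record.mz + 0.5, 1.0)]), small_list)
        assert any(m.record == record for m in cands.matches)
        cands = coarse_annotate(_exp([Peak(record.mz + 0.5001, 1.0)]),
                                small_list)
        assert not any(m.record == record for m in cands.matches)

    def test_shared_mz_yields_two_candidates(self, n_list):
        by_mz = {}
        for record in n_list.records:
            by_mz.setdefault(round(record.mz, 4), []).append(record)
        mz, group = next((k, v) for k, v in by_mz.items() if len(v) > 1)
        cands = coarse_annotate(_exp([Peak(mz, 1.0)]), n_list)
        matched = [m.record for m in cands.matches if m.peak.mz == mz]
        assert set(group) <= set(matched)


class TestCalibrate:
    def test_planted_drift_recovered(self, n_list):
        spec = build_study_spec(n_list, seed=7, series=["wt"], n_glycans=40)
        exp = simulate_experiment(spec, "wt", 1)
        model = calibrate(coarse_annotate(exp, n_list))
        assert model.intercept == pytest.approx(spec.drift.intercept, rel=0.05)
        assert model.slope == pytest.approx(spec.drift.slope, rel=0.05)
        assert model.standards_confirmed

    def test_zero_drift_gives_identity_like_fit(self, n_list):
        spec = build_study_spec(n_list, seed=7, series=["wt"], n_glycans=40,
                                drift=DriftSpec(0.0, 0.0))
        exp = simulate_experiment(noise_free(spec), "wt", 1)
        model = calibrate(coarse_annotate(exp, n_list))
        assert abs(model.intercept) < 1e-6
        assert abs(model.slope) < 1e-9

    def test_single_match_falls_back_to_identity(self, small_list):
        record = small_list.records[0]
        exp = _exp([Peak(record.mz + 0.01, 1.0)])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = calibrate(coarse_annotate(exp, small_list))
        assert model.is_identity
        assert any("identity" in str(w.message) for w in caught)


class TestRefine:
    def test_far_off_line_candidate_rejected(self, small_list):
        record = small_list.records[3]
        model = CalibrationModel(acceptance=0.01)
        cands = coarse_annotate(
            _exp([Peak(record.mz + 0.4, 1.0)]), small_list)
        result = refine_annotate(cands, model)
        assert not result.accepted

    def test_every_record_present_with_zero_for_undetected(self, small_list):
        cands = coarse_annotate(_exp([]), small_list)
        result = refine_annotate(cands, CalibrationModel())
        assert len(result.annotations) == len(small_list.records)
        assert all(a.quantity == 0 for a in result.annotations)

    def test_planted_peaks_fully_accepted_under_drift(self, n_list):
        spec = noise_free(build_study_spec(n_list, seed=3, series=["wt"],
                                           n_glycans=40))
        exp = simulate_experiment(spec, "wt", 1)
        result = annotate_experiment(exp, n_list)
        planted_mz = {round(r.mz, 4) for r in spec.records_by_label.values()
                      if r.label in spec.planted["wt"]}
        accepted_mz = {round(a.record.mz, 4) for a in result.accepted}
        assert planted_mz <= accepted_mz
        # contaminants never produce an accepted record
        assert accepted_mz <= planted_mz


class TestQuantify:
    def _result(self, small_list, area, std_area, is_pmol, protein):
        record = small_list.records[0]
        std = small_list.standards[0]
        exp = _exp([Peak(record.mz, area), Peak(std.mz, std_area)],
                   internal_standard_pmol=is_pmol, protein_ug=protein)
        cands = coarse_annotate(exp, small_list)
        result = refine_annotate(cands, CalibrationModel(acceptance=0.01))
        return quantify(result, cands), record

    def test_equal_areas_identity_case(self, small_list):
        result, record = self._result(small_list, 100.0, 100.0, 10.0, 100.0)
        got = {a.record.label: a.quantity for a in result.accepted}
        assert got[record.label] == pytest.approx(10.0)

    def test_double_area_half_protein(self, small_list):
        result, record = self._result(small_list, 200.0, 100.0, 5.0, 50.0)
        got = {a.record.label: a.quantity for a in result.accepted}
        assert got[record.label] == pytest.approx(20.0)

    def test_zero_area_gives_zero(self, small_list):
        result, record = self._result(small_list, 0.0, 100.0, 10.0, 100.0)
        got = {a.record.label: a.quantity for a in result.annotations
               if a.record == record}
        assert got[record.label] == 0.0

    def test_missing_standard_is_hard_error(self, small_list):
        record = small_list.records[0]
        exp = _exp([Peak(record.mz, 5.0)])
        cands = coarse_annotate(exp, small_list)
        result = refine_annotate(cands, CalibrationModel())
        with pytest.raises(QuantificationError):
            quantify(result, cands)


class TestUniqueMz:
    def test_shared_mz_counts_once(self, n_list):
        by_mz = {}
        for record in n_list.records:
            by_mz.setdefault(round(record.mz, 4), []).append(record)
        all_mz = sorted(by_mz)
        # a shared m/z with no other record within 0.01 Da
        mz, group = next(
            (k, v) for k, v in sorted(by_mz.items()) if len(v) > 1
            and all(abs(k - other) > 0.01 for other in all_mz if other != k))
        std = n_list.standards[0]
        exp = _exp([Peak(mz, 5.0), Peak(std.mz, 5.0)], tolerance=0.005)
        result = annotate_experiment(exp, n_list, calibration=False)
        assert len(result.accepted) == len(group) >= 2
        assert count_unique_mz(result) == 1

    def test_empty_result_counts_zero(self, small_list):
        cands = coarse_annotate(_exp([]), small_list)
        result = refine_annotate(cands, CalibrationModel())
        assert count_unique_mz(result) == 0

    def test_all_planted_recovered(self, n_list):
        spec = noise_free(build_study_spec(n_list, seed=11, series=["wt"],
                                           n_glycans=12))
        exp = simulate_experiment(spec, "wt", 1)
        result = annotate_experiment(exp, n_list)
        assert count_unique_mz(result) == 12
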