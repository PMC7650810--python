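"""Series statistics, the t-test oracle, and result files."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from glycotag.annotate import annotate_experiment, AnnotationResult
from glycotag.expression import (DesignError, SeriesDesign, aggregate_stats,
                                 read_exp_list, read_out_list, students_t,
                                 total_quantity, write_cluster_input,
                                 write_exp_list, write_out_list)
from glycotag.simulate import build_study_spec, noise_free, simulate_experiment


@pytest.fixture(scope="module")
def study(small_list):
    """A three-series noise-free study annotated end to end."""
    spec = noise_free(build_study_spec(
        small_list, seed=5, series=["wt(-)", "NPC(-)", "NPC(+)"],
        n_glycans=8, fold_change=1.5))
    results = []
    for series in spec.planted:
        for rep in (1, 2, 3):
            exp = simulate_experiment(spec, series, rep)
            results.append(annotate_experiment(exp, small_list))
    return spec, results


class TestStudentsT:
    def test_textbook_oracle(self):
        """{1,2,3} vs {4,5,6}: pooled s^2 = 1, t = -3/sqrt(2/3), df = 4."""
        result = students_t([1, 2, 3], [4, 5, 6])
        assert result.t == pytest.approx(-3.6742346141747673, abs=1e-10)
        assert result.p == pytest.approx(0.021311641128756713, abs=1e-10)
        assert result.df == 4

    def test_identical_samples_null_case(self):
        result = students_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert result.t == 0.0 and result.p == 1.0

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(1.0, 2.0, size=5)
            ours = students_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)
            welch = students_t(a, b, welch=True)
            ref_w = sps.ttest_ind(a, b, equal_var=False)
            assert welch.t == pytest.approx(ref_w.statistic, abs=1e-12)
            assert welch.p == pytest.approx(ref_w.pvalue, abs=1e-12)


class TestAggregate:
    def test_three_series_yield_three_pairwise_tests(self, study):
        _, results = study
        table = aggregate_stats(results)
        assert len(table.series_pairs) == 3
        assert all(len(row.tests) == 3 for row in table.rows)

    def test_sample_sd_and_cv(self, small_list):
        spec = build_study_spec(small_list, seed=9, series=["wt"],
                                n_glycans=4)
        results = [annotate_experiment(simulate_experiment(spec, "wt", r),
                                       small_list) for r in (1, 2, 3)]
        table = aggregate_stats(results)
        row = next(r for r in table.rows
                   if r.record.label in spec.planted["wt"])
        values = np.array([row.quantities[e] for e in table.experiments])
        assert row.mean["wt"] == pytest.approx(values.mean())
        assert row.sd["wt"] == pytest.approx(values.std(ddof=1))
        assert row.cv["wt"] == pytest.approx(
            values.std(ddof=1) / values.mean())

    def test_undetected_glycan_has_blank_cv(self, study):
        _, results = study
        table = aggregate_stats(results)
        zero_row = next(r for r in table.rows
                        if all(v == 0 for v in r.quantities.values()))
        assert all(cv is None for cv in zero_row.cv.values())
        assert all(t.t == 0 and t.p == 1 for t in zero_row.tests.values())

    def test_singleton_series_blanks_and_warns(self, small_list):
        spec = noise_free(build_study_spec(small_list, seed=1,
                                           series=["a", "b"], n_glycans=3,
                                           replicates=1))
        results = [annotate_experiment(simulate_experiment(spec, s, 1),
                                       small_list) for s in ("a", "b")]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = aggregate_stats(results)
        assert any("single experiment" in str(w.message) for w in caught)
        row = table.rows[0]
        assert row.sd["a"] is None
        assert all(math.isnan(t.t) for t in row.tests.values())

    def test_internal_standard_not_in_table(self, study, small_list):
        _, results = study
        table = aggregate_stats(results)
        std_mz = small_list.standards[0].mz
        assert all(abs(row.record.mz - std_mz) > 1e-6 for row in table.rows)


class TestResultFiles:
    def test_out_list_round_trip_bit_exact(self, study, tmp_path):
        _, results = study
        path = tmp_path / "out_list.csv"
        write_out_list(results[0], path)
        rows = read_out_list(path)
        got = {r["composition"]: r["pmol_per_100ug"] for r in rows}
        for annotation in results[0].annotations:
            assert got[str(annotation.record.composition)] == annotation.quantity

    def test_conservation_between_files(self, study, tmp_path):
        """Total quantity per experiment agrees between out_list and
        exp_list exactly."""
        _, results = study
        table = aggregate_stats(results)
        write_exp_list(table, tmp_path / "exp_list.csv")
        again = read_exp_list(tmp_path / "exp_list.csv")
        for res in results:
            out_total = total_quantity(res)
            exp_total = sum(row.quantities[res.name] for row in again.rows)
            assert exp_total == pytest.approx(out_total, abs=1e-12)

    def test_exp_list_column_arity(self, study, tmp_path):
        _, results = study
        table = aggregate_stats(results)
        path = tmp_path / "exp_list.csv"
        write_exp_list(table, path)
        header = path.read_text().splitlines()[0].split(",")
        assert sum(1 for c in header if c.startswith("mean[")) == 3
        assert sum(1 for c in header if c.startswith("sd[")) == 3
        assert sum(1 for c in header if c.startswith("t[")) == 3
        assert sum(1 for c in header if c.startswith("p[")) == 3

    def test_cluster_input_format(self, study, tmp_path):
        _, results = study
        table = aggregate_stats(results)
        path = tmp_path / "cluster.txt"
        write_cluster_input(table, path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        assert header[0] == "GLYCAN"
        assert header[1:] == table.experiments
        assert len(lines) == len(table.rows) + 1
        for line in lines[1:]:
            cells = line.split("\t")
            assert len(cells) == len(header)
            for cell in cells[1:]:
                float(cell)

    def test_exp_list_round_trip_statistics(self, study, tmp_path):
        _, results = study
        table = aggregate_stats(results)
        path = tmp_path / "exp_list.csv"
        write_exp_list(table, path)
        again = read_exp_list(path)
        assert again.design.series_names == table.design.series_names
        for row, row2 in zip(table.rows, again.rows):
            for series in table.design.series_names:
                assert row2.mean[series] == pytest.approx(row.mean[series])
            for pair, test in row.tests.items():
                t2 = row2.tests[pair]
                if math.isnan(test.t):
                    assert math.isnan(t2.t)
                else:
                    assert t2.t == pytest.approx(test.t, abs=1e-9)


def test_mismatched_lists_rejected(small_list, n_list):
    spec = noise_free(build_study_spec(small_list, seed=2, series=["a"],
                                       n_glycans=3))
    r1 = annotate_experiment(simulate_experiment(spec, "a", 1), small_list)
    r2 = annotate_experiment(simulate_experiment(spec, "a", 2), n_list)
    with pytest.raises(DesignError, match="different lists"):
        aggregate_stats([r1, r2])
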