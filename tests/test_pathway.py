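"""Pathway map parsing, expression binding and the highlight rule."""

import pytest

from glycotag.annotate import annotate_experiment
from glycotag.composition import Core
from glycotag.expression import aggregate_stats
from glycotag.pathway import (PathwayFormatError, bind_expression,
                              default_pathway_map, read_pathway_map,
                              render_pathway_html)
from glycotag.simulate import SimulationSpec, noise_free, simulate_experiment


@pytest.fixture(scope="module")
def map_study(n_list):
    """A two-series study planting exactly two compositions that appear as
    cells of the bundled map, with a 2-fold increase at 1% noise, n=3."""
    pmap = default_pathway_map()
    records = [r for r in n_list.records
               if str(r.composition) in ("C:20000", "C:22020")]
    planted_labels = [r.label for r in records]
    base = {planted_labels[0]: 10.0, planted_labels[1]: 4.0}
    spec = SimulationSpec(
        glycan_list=n_list,
        planted={"wt(-)": base,
                 "NPC(-)": {k: 2.0 * v for k, v in base.items()}},
        seed=17, area_sigma=0.01, n_contaminants=0)
    results = []
    for series in spec.planted:
        for rep in (1, 2, 3):
            results.append(annotate_experiment(
                simulate_experiment(spec, series, rep), n_list))
    return pmap, aggregate_stats(results), spec


def test_bundled_map_parses_with_both_sections():
    pmap = default_pathway_map()
    cores = {c.composition.core for c in pmap.cells}
    assert Core.C in cores                      # protein-linked section
    assert {Core.N1, Core.N2} <= cores          # free-glycan section
    assert pmap.arrows, "expected arrow connector cells"
    locs = {c.localization for c in pmap.cells}
    assert {"ER", "Golgi", "cytoplasm", "lysosome"} <= locs


def test_bad_notation_cell_reports_coordinate(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("x,\nHM,\nC:2212X,\nER,\n")
    with pytest.raises(PathwayFormatError, match="A3"):
        read_pathway_map(path)


def test_unknown_localization_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("x,\nHM,\nC:20000,\nnucleus,\n")
    with pytest.raises(PathwayFormatError, match="localization"):
        read_pathway_map(path)


def test_unmatched_cells_marked_not_measured(map_study):
    pmap, table, _ = map_study
    bound = bind_expression(pmap, table, ("wt(-)", "NPC(-)"))
    free_cells = [c for c in pmap.cells if c.composition.core is not Core.C]
    assert free_cells
    for cell in free_cells:
        assert not bound.payload(cell).measured


def test_binding_is_idempotent(map_study):
    pmap, table, _ = map_study
    once = bind_expression(pmap, table, ("wt(-)", "NPC(-)"))
    twice = bind_expression(once.pathway, table, ("wt(-)", "NPC(-)"))
    assert once.payloads == twice.payloads


def _highlighted(bound, threshold=0.05):
    return {
        (c.col, c.row): p
        for (c, p) in ((cell, bound.payload(cell)) for cell in
                       bound.pathway.cells)
        if p.measured and p.p is not None and p.p < threshold
        and p.diff not in (None, 0.0)}


def test_planted_two_fold_increase_highlights_exactly_those_cells(map_study):
    pmap, table, spec = map_study
    bound = bind_expression(pmap, table, ("wt(-)", "NPC(-)"))
    planted_cells = {(c.col, c.row) for c in pmap.cells
                     if str(c.composition) in ("C:20000", "C:22020")}
    marked = _highlighted(bound)
    assert set(marked) == planted_cells
    assert all(p.diff > 0 for p in marked.values())
    for cell in pmap.cells:
        payload = bound.payload(cell)
        if (cell.col, cell.row) in planted_cells:
            assert payload.ratio == pytest.approx(2.0, rel=0.05)


def test_identical_series_highlight_nothing(n_list):
    pmap = default_pathway_map()
    records = [r for r in n_list.records if str(r.composition) == "C:20000"]
    base = {records[0].label: 10.0}
    spec = noise_free(SimulationSpec(
        glycan_list=n_list, planted={"a": dict(base), "b": dict(base)},
        seed=3, n_contaminants=0))
    results = [annotate_experiment(simulate_experiment(spec, s, r), n_list)
               for s in ("a", "b") for r in (1, 2, 3)]
    table = aggregate_stats(results)
    bound = bind_expression(pmap, table, ("a", "b"))
    assert not _highlighted(bound)
    for cell in pmap.cells:
        payload = bound.payload(cell)
        if payload.measured:
            assert payload.diff == 0


def test_threshold_is_strict(map_study, tmp_path):
    """A cell whose p equals the threshold exactly is not highlighted: the
    rule is strictly p < threshold."""
    pmap, table, _ = map_study
    bound = bind_expression(pmap, table, ("wt(-)", "NPC(-)"))
    marked = _highlighted(bound)
    assert marked
    p_min = min(p.p for p in marked.values())
    render_pathway_html(bound, "values", tmp_path / "default.html")
    render_pathway_html(bound, "values", tmp_path / "tight.html",
                        threshold=p_min)
    n_default = (tmp_path / "default.html").read_text().count("color:#c00000")
    n_tight = (tmp_path / "tight.html").read_text().count("color:#c00000")
    assert n_default == len(marked)
    assert n_tight == sum(1 for p in marked.values() if p.p < p_min)


def test_rendering_is_total_in_both_modes(map_study, tmp_path):
    pmap, table, _ = map_study
    bound = bind_expression(pmap, table, ("wt(-)", "NPC(-)"))
    for mode in ("bars", "values"):
        out = tmp_path / f"{mode}.html"
        render_pathway_html(bound, mode, out)
        text = out.read_text()
        assert "<table>" in text
        assert "not measured" in text
    # three bars per measured cell in bars mode would need 3 series; here 2
    assert tmp_path.joinpath("bars.html").read_text().count("class='bars'") \
        == sum(1 for p in bound.payloads.values() if p.measured)


def test_unknown_series_pair_rejected(map_study):
    pmap, table, _ = map_study
    with pytest.raises(PathwayFormatError, match="series"):
        bind_expression(pmap, table, ("wt(-)", "nope"))
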