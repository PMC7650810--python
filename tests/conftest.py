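import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def n_list():
    """The bundled default N-glycan list (900 records)."""
    from glycotag import enumerate_glycans

    return enumerate_glycans("N")


@pytest.fixture(scope="session")
def f_list():
    """The bundled default free-N-glycan list (1770 records)."""
    from glycotag import enumerate_glycans

    return enumerate_glycans("F")


@pytest.fixture(scope="session")
def small_list(n_list):
    """A 12-record sub-list with distinct m/z, for fast pipeline tests."""
    from glycotag.listing import GlycanList
    from glycotag.simulate import pick_planted_records

    records = pick_planted_records(n_list, 12)
    return GlycanList(kind="N", standards=list(n_list.standards),
                      records=records)


def write_peaklist_text(path, rows, meta=("10", "0.5", "50", "1", "wt(-)"),
                        delimiter=","):
    """A minimal hand-rolled peak-list file in the 3-header-row dialect."""
    lines = [delimiter.join(["m/z", "", "", "", "", "", "area"]),
             delimiter.join(meta),
             ""]
    for mz, area in rows:
        cells = [str(mz)] + [""] * 5 + [str(area)]
        lines.append(delimiter.join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
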