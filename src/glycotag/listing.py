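"""Semi-comprehensive glycan list: enumeration and the list-CSV dialect.

The list file is the database searched during annotation:

* row 1 — a single ``N`` or ``F`` character (N-glycan or free-N-glycan list);
* row 2 — internal-standard labels and m/z values, comma separated
  (``label,mz[,label,mz...]``);
* rows 3+ — one record per line: composition (``core:five-digit``),
  theoretical m/z, type code.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .composition import Core, GlycanComposition, parse_composition
from .masses import MassConfig, a2gn1_mz, composition_mass
from .taxonomy import StructureHints, Taxonomy, default_taxonomy

#: m/z values are written (and compared) at this precision.
MZ_DECIMALS = 4


class ListFormatError(ValueError):
    """Malformed glycan-list CSV."""


@dataclass(frozen=True)
class GlycanRecord:
    """One row of a glycan list."""

    composition: GlycanComposition
    type_code: str
    mz: float

    @property
    def label(self) -> str:
        return f"{self.composition}|{self.type_code}"

    def key(self) -> tuple:
        return (self.composition, self.type_code, round(self.mz, MZ_DECIMALS))


@dataclass(frozen=True)
class InternalStandard:
    label: str
    mz: float


@dataclass
class GlycanList:
    """A glycan list: kind flag, internal standards, ordered records."""

    kind: str                      # "N" | "F"
    standards: list[InternalStandard] = field(default_factory=list)
    records: list[GlycanRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("N", "F"):
            raise ListFormatError(f"kind must be 'N' or 'F', got {self.kind!r}")
        allowed = {Core.C} if self.kind == "N" else {Core.N1, Core.N2}
        for rec in self.records:
            if rec.composition.core not in allowed:
                raise ListFormatError(
                    f"record {rec.composition} has core "
                    f"{rec.composition.core.value}, illegal in a "
                    f"{self.kind} list")
        keys = [(r.composition, r.type_code) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ListFormatError("records are not unique on (composition, type)")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GlycanList)
                and self.kind == other.kind
                and self.standards == other.standards
                and [r.key() for r in self.records]
                == [r.key() for r in other.records])


def default_internal_standard(cfg: MassConfig | None = None) -> InternalStandard:
    """The A2GN1 spike-in at its theoretical m/z under ``cfg``."""
    return InternalStandard("A2GN1", round(a2gn1_mz(cfg), MZ_DECIMALS))


def enumerate_glycans(
    kind: str,
    taxonomy: Taxonomy | None = None,
    cfg: MassConfig | None = None,
    standards: list[InternalStandard] | None = None,
) -> GlycanList:
    """Expand a rules table into a sorted, mass-annotated glycan list.

    Records are the cartesian expansion of every type's ranges filtered by
    the structural constraints, each classified by its generating type and
    sorted by (taxonomy order, m/z).  Deterministic: identical rules yield
    byte-identical CSV output.
    """
    if kind not in ("N", "F"):
        raise ValueError(f"kind must be 'N' or 'F', got {kind!r}")
    taxonomy = taxonomy if taxonomy is not None else default_taxonomy(kind)
    cfg = cfg or MassConfig.default()
    allowed = {Core.C} if kind == "N" else {Core.N1, Core.N2}
    records: list[GlycanRecord] = []
    seen: set[tuple[GlycanComposition, str]] = set()
    for gtype in taxonomy:
        if gtype.core not in allowed:
            raise ListFormatError(
                f"type {gtype.code} has core {gtype.core.value}, "
                f"inconsistent with kind {kind!r}")
        for comp, _hints in gtype.expand():
            key = (comp, gtype.code)
            if key in seen:
                continue
            seen.add(key)
            records.append(GlycanRecord(
                composition=comp,
                type_code=gtype.code,
                mz=round(composition_mass(comp, cfg), MZ_DECIMALS)))
    records.sort(key=lambda r: (taxonomy.order_key(r.type_code,
                                                   r.composition.core), r.mz))
    if standards is None:
        standards = [default_internal_standard(cfg)]
    return GlycanList(kind=kind, standards=standards, records=records)


# ---------------------------------------------------------------------------
# list CSV dialect


def write_list_csv(glist: GlycanList, path: str | Path) -> None:
    if not glist.records:
        raise ListFormatError("refusing to write an empty glycan list")
    if not glist.standards:
        warnings.warn(
            "glycan list has no internal standard; downstream "
            "quantification will be impossible", stacklevel=2)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([glist.kind])
        std_row: list[str] = []
        for std in glist.standards:
            std_row += [std.label, f"{std.mz:.{MZ_DECIMALS}f}"]
        writer.writerow(std_row)
        for rec in glist.records:
            writer.writerow([str(rec.composition),
                             f"{rec.mz:.{MZ_DECIMALS}f}",
                             rec.type_code])


def read_list_csv(path: str | Path) -> GlycanList:
    """Inverse of :func:`write_list_csv`; tolerant of trailing blank lines."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    while rows and not any(cell.strip() for cell in rows[-1]):
        rows.pop()
    if len(rows) < 2:
        raise ListFormatError(f"{path}: need a kind row and a standards row")
    kind = rows[0][0].strip()
    if kind not in ("N", "F"):
        raise ListFormatError(f"{path}: unknown kind flag {kind!r}")
    std_cells = [c.strip() for c in rows[1] if c.strip()]
    if len(std_cells) % 2:
        raise ListFormatError(f"{path}: standards row must hold label,mz pairs")
    standards = []
    for label, mz_text in zip(std_cells[::2], std_cells[1::2]):
        try:
            standards.append(InternalStandard(label, float(mz_text)))
        except ValueError:
            raise ListFormatError(
                f"{path}: non-numeric internal-standard m/z {mz_text!r}")
    records = []
    for lineno, row in enumerate(rows[2:], start=3):
        if len(row) < 3:
            raise ListFormatError(f"{path}:{lineno}: expected 3 columns")
        comp = parse_composition(row[0].strip())
        try:
            mz = float(row[1])
        except ValueError:
            raise ListFormatError(
                f"{path}:{lineno}: non-numeric m/z {row[1]!r}")
        records.append(GlycanRecord(composition=comp, type_code=row[2].strip(),
                                    mz=mz))
    return GlycanList(kind=kind, standards=standards, records=records)
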