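"""Structural-type taxonomy: data-driven type definitions and classification.

Each type is one row of a human-editable rules table (CSV) giving min/max
ranges per monosaccharide class plus structural attributes (antenna count,
mannose-arm size, LacdiNAc units, fucosylation site).  The bundled default
tables define 43 N-glycan types and 82 free-N-glycan types; users can edit
or extend them — the enumerator and classifier are entirely table-driven.

Structural constraints applied on top of the ranges:

* capped units (Gal + GalNAc) never exceed the antenna count;
* sialic acids never exceed the number of capped units;
* fucoses never exceed the available attachment sites (core GlcNAc if the
  core retains it, antenna GlcNAcs, capped units), nor the global maximum;
* a type with ``fuc_site = core`` places fucose on the reducing-end GlcNAc
  only, so it is empty on the N1 core;
* O-acetyl groups sit on sialic acids: at most two, and never more than the
  number of sialic acids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterator

from .composition import Core, GlycanComposition

#: Global cap on fucose residues per glycan.
MAX_FUCOSE = 3
#: Global cap on O-acetyl modifications per glycan.
MAX_ACETYL = 2

CLASSES = ("HM", "glucosylated-HM", "PM", "hybrid", "complex")


class TaxonomyError(ValueError):
    """Invalid rules table or unclassifiable composition."""


@dataclass(frozen=True)
class GlycanType:
    """One structural type: a row of the rules table."""

    code: str
    glycan_class: str
    core: Core
    antennae_min: int = 0
    antennae_max: int = 0
    man_min: int = 0
    man_max: int = 0
    gal_min: int = 0
    gal_max: int = 0
    galnac_min: int = 0
    galnac_max: int = 0
    neuac_min: int = 0
    neuac_max: int = 0
    neugc_min: int = 0
    neugc_max: int = 0
    fuc_min: int = 0
    fuc_max: int = 0
    fuc_site: str = "any"      # "any" | "core"
    acetyl_min: int = 0
    acetyl_max: int = 0

    def __post_init__(self) -> None:
        if self.glycan_class not in CLASSES:
            raise TaxonomyError(
                f"type {self.code}: unknown class {self.glycan_class!r}")
        if self.fuc_site not in ("any", "core"):
            raise TaxonomyError(f"type {self.code}: bad fuc_site {self.fuc_site!r}")
        for lo, hi, what in (
            (self.antennae_min, self.antennae_max, "antennae"),
            (self.man_min, self.man_max, "man"),
            (self.gal_min, self.gal_max, "gal"),
            (self.galnac_min, self.galnac_max, "galnac"),
            (self.neuac_min, self.neuac_max, "neuac"),
            (self.neugc_min, self.neugc_max, "neugc"),
            (self.fuc_min, self.fuc_max, "fuc"),
            (self.acetyl_min, self.acetyl_max, "acetyl"),
        ):
            if lo > hi:
                raise TaxonomyError(
                    f"type {self.code}: empty {what} range [{lo}, {hi}]")
        if self.fuc_max > MAX_FUCOSE:
            raise TaxonomyError(
                f"type {self.code}: fuc_max {self.fuc_max} exceeds global "
                f"maximum {MAX_FUCOSE}")
        if self.acetyl_max > MAX_ACETYL:
            raise TaxonomyError(
                f"type {self.code}: acetyl_max {self.acetyl_max} exceeds "
                f"global maximum {MAX_ACETYL}")

    # ------------------------------------------------------------------
    def expand(self) -> Iterator[tuple[GlycanComposition, "StructureHints"]]:
        """Yield every composition this type admits, with structure hints."""
        core = self.core
        core_sites = 1 if core.has_core_fucose_site else 0
        for ant in range(self.antennae_min, self.antennae_max + 1):
            for man in range(self.man_min, self.man_max + 1):
                for gal in range(self.gal_min, min(self.gal_max, ant) + 1):
                    gn_hi = min(self.galnac_max, ant - gal)
                    for gnac in range(self.galnac_min, gn_hi + 1):
                        caps = gal + gnac
                        for na in range(self.neuac_min,
                                        min(self.neuac_max, caps) + 1):
                            ng_hi = min(self.neugc_max, caps - na)
                            for ngc in range(self.neugc_min, ng_hi + 1):
                                yield from self._expand_tail(
                                    ant, man, gal, gnac, na, ngc, core_sites)

    def _expand_tail(self, ant, man, gal, gnac, na, ngc, core_sites):
        if self.fuc_site == "core":
            fuc_hi = min(self.fuc_max, core_sites)
        else:
            fuc_hi = min(self.fuc_max, MAX_FUCOSE,
                         core_sites + ant + gal + gnac)
        sial = na + ngc
        ac_hi = min(self.acetyl_max, MAX_ACETYL, sial)
        for fuc in range(self.fuc_min, fuc_hi + 1):
            for ac in range(self.acetyl_min, ac_hi + 1):
                comp = GlycanComposition(
                    core=self.core,
                    hex=man + gal,
                    hexnac=ant + gnac,
                    fuc=fuc,
                    neuac=na,
                    neugc=ngc,
                    acetyl=ac,
                )
                yield comp, StructureHints(
                    antennae=ant, mannose_arm=man, galactose=gal,
                    galnac=gnac)

    def admits(self, comp: GlycanComposition,
               hints: "StructureHints | None" = None) -> bool:
        """Whether ``comp`` (optionally with structure hints) fits this type."""
        if comp.core is not self.core:
            return False
        candidates = [hints] if hints is not None else self._decompositions(comp)
        return any(self._admits_split(comp, h) for h in candidates)

    def _admits_split(self, comp: GlycanComposition, h: "StructureHints") -> bool:
        if comp.hexnac != h.antennae + h.galnac or comp.hex != h.mannose_arm + h.galactose:
            return False
        if not (self.antennae_min <= h.antennae <= self.antennae_max
                and self.man_min <= h.mannose_arm <= self.man_max
                and self.gal_min <= h.galactose <= self.gal_max
                and self.galnac_min <= h.galnac <= self.galnac_max):
            return False
        caps = h.galactose + h.galnac
        if caps > h.antennae:
            return False
        if not (self.neuac_min <= comp.neuac <= self.neuac_max
                and self.neugc_min <= comp.neugc <= self.neugc_max
                and comp.sialic <= caps):
            return False
        core_sites = 1 if self.core.has_core_fucose_site else 0
        if self.fuc_site == "core":
            fuc_hi = min(self.fuc_max, core_sites)
        else:
            fuc_hi = min(self.fuc_max, MAX_FUCOSE,
                         core_sites + h.antennae + caps)
        if not self.fuc_min <= comp.fuc <= fuc_hi:
            return False
        ac_hi = min(self.acetyl_max, MAX_ACETYL, comp.sialic)
        return self.acetyl_min <= comp.acetyl <= ac_hi

    def _decompositions(self, comp):
        # all (antennae, man, gal, gnac) splits consistent with the counts
        for ant in range(self.antennae_min, self.antennae_max + 1):
            gnac = comp.hexnac - ant
            if gnac < 0:
                continue
            gal_top = comp.hex if comp.hex >= 0 else 0
            for gal in range(0, gal_top + 1):
                yield StructureHints(antennae=ant, mannose_arm=comp.hex - gal,
                                     galactose=gal, galnac=gnac)


@dataclass(frozen=True)
class StructureHints:
    """Structural attributes resolving composition-level ambiguity."""

    antennae: int = 0
    mannose_arm: int = 0
    galactose: int = 0
    galnac: int = 0


class Taxonomy:
    """An ordered collection of :class:`GlycanType` rows."""

    def __init__(self, types: list[GlycanType]):
        codes = [t.code for t in types]
        dupes = {c for c in codes if codes.count(c) > 1}
        # the same code may appear once per core in FNG tables
        per_core = [(t.code, t.core) for t in types]
        if len(set(per_core)) != len(per_core):
            raise TaxonomyError(f"duplicate (code, core) rows: {sorted(dupes)}")
        self.types = list(types)
        self._order = {(t.code, t.core): i for i, t in enumerate(types)}

    def __len__(self) -> int:
        return len(self.types)

    def __iter__(self):
        return iter(self.types)

    @property
    def codes(self) -> list[str]:
        return [t.code for t in self.types]

    def order_key(self, code: str, core: Core) -> int:
        return self._order[(code, core)]

    def classify(self, comp: GlycanComposition,
                 hints: StructureHints | None = None) -> GlycanType:
        """The unique type admitting ``comp`` (with hints to disambiguate).

        Raises :class:`TaxonomyError` when no type matches (never silently
        drops a record) or when several match and no hints were given.
        """
        matches = [t for t in self.types if t.admits(comp, hints)]
        if not matches:
            raise TaxonomyError(f"composition {comp} matches no type")
        if len(matches) > 1:
            raise TaxonomyError(
                f"composition {comp} is ambiguous between "
                f"{[t.code for t in matches]}; pass structure hints")
        return matches[0]

    # -- CSV round trip -------------------------------------------------
    _COLUMNS = [f.name for f in fields(GlycanType)]

    @classmethod
    def from_csv(cls, path: str | Path) -> "Taxonomy":
        with open(path, newline="") as fh:
            return cls._from_reader(csv.DictReader(fh), str(path))

    @classmethod
    def _from_reader(cls, reader: csv.DictReader, source: str) -> "Taxonomy":
        types = []
        for row in reader:
            kwargs = {}
            for col in cls._COLUMNS:
                if col not in row or row[col] == "":
                    raise TaxonomyError(f"{source}: missing column {col!r}")
                value = row[col]
                if col in ("code", "glycan_class", "fuc_site"):
                    kwargs[col] = value
                elif col == "core":
                    kwargs[col] = Core(value)
                else:
                    kwargs[col] = int(value)
            types.append(GlycanType(**kwargs))
        if not types:
            raise TaxonomyError(f"{source}: empty rules table")
        return cls(types)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(self._COLUMNS)
            for t in self.types:
                writer.writerow(
                    [getattr(t, c).value if c == "core" else getattr(t, c)
                     for c in self._COLUMNS])


def _bundled(name: str) -> Taxonomy:
    ref = resources.files("glycotag.data").joinpath(name)
    with resources.as_file(ref) as path:
        return Taxonomy.from_csv(path)


def default_taxonomy(kind: str) -> Taxonomy:
    """The bundled rules table for ``kind`` ``"N"`` (43 types) or ``"F"`` (82)."""
    if kind == "N":
        return _bundled("rules_n.csv")
    if kind == "F":
        return _bundled("rules_f.csv")
    raise ValueError(f"kind must be 'N' or 'F', got {kind!r}")
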