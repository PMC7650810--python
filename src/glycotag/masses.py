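"""Mass configuration and theoretical m/z computation.

The default preset models the chemistry of glycoblotting-based MALDI-TOF
analysis: glycans labelled at the reducing end with aoWR (an aminooxy
tryptophanyl-arginine tag with high proton affinity) and sialic acid
carboxylates neutralized by methyl esterification.  Every increment is a
named entry so other chemistries (2-AB, RapiFluor-MS, linkage-specific
alkylamidation) are expressible by configuration alone.

The reported m/z is that of the singly protonated labelled glycan,
``[M+H]+`` (``adduct`` = proton mass); set ``adduct`` to 0 for neutral
labelled masses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

from . import chem
from .composition import Core, GlycanComposition


class MassConfigError(KeyError):
    """A required mass constant is missing from a configuration file."""


_FIELDS = (
    "hex", "hexnac", "fuc", "neuac", "neugc",
    "sialic_derivatization", "acetyl", "water", "label", "adduct",
)


@dataclass(frozen=True)
class MassConfig:
    """Monoisotopic mass constants (Da) for theoretical m/z computation.

    ``sialic_derivatization`` is added once per NeuAc *and* per NeuGc;
    ``label`` is the net reducing-end label increment (reagent minus water
    for a condensation); ``adduct`` is the ionization increment and may be 0.
    """

    hex: float
    hexnac: float
    fuc: float
    neuac: float
    neugc: float
    sialic_derivatization: float
    acetyl: float
    water: float
    label: float
    adduct: float
    name: str = "custom"

    def __post_init__(self) -> None:
        for field in ("hex", "hexnac", "fuc", "neuac", "neugc", "acetyl", "water"):
            if getattr(self, field) <= 0:
                raise ValueError(f"mass constant {field!r} must be positive")
        # label / derivatization / adduct may be zero (bare free glycans)
        for field in ("sialic_derivatization", "label", "adduct"):
            if getattr(self, field) < 0:
                raise ValueError(f"mass constant {field!r} must not be negative")

    @classmethod
    def default(cls) -> "MassConfig":
        """The ``aoWR-methylester`` preset, derived from elemental formulas."""
        return cls(
            hex=chem.residue_mass("hex"),
            hexnac=chem.residue_mass("hexnac"),
            fuc=chem.residue_mass("fuc"),
            neuac=chem.residue_mass("neuac"),
            neugc=chem.residue_mass("neugc"),
            sialic_derivatization=chem.monoisotopic_mass(
                chem.INCREMENT_FORMULA["methyl_ester"]),
            acetyl=chem.monoisotopic_mass(chem.INCREMENT_FORMULA["acetyl"]),
            water=chem.monoisotopic_mass(chem.INCREMENT_FORMULA["water"]),
            label=chem.monoisotopic_mass(chem.AOWR_FORMULA)
                  - chem.monoisotopic_mass(chem.INCREMENT_FORMULA["water"]),
            adduct=chem.PROTON_MASS,
            name="aoWR-methylester",
        )

    @classmethod
    def free_glycan(cls) -> "MassConfig":
        """Unlabelled, underivatized neutral glycan masses."""
        return replace(cls.default(), name="free-glycan",
                       label=0.0, adduct=0.0, sialic_derivatization=0.0)

    # -- flat key=value text config ------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "MassConfig":
        values: dict[str, float] = {}
        name = Path(path).stem
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = (part.strip() for part in line.split("=", 1))
            except ValueError:
                raise MassConfigError(f"{path}:{lineno}: expected 'key = value'")
            if key == "name":
                name = value
            else:
                values[key] = float(value)
        missing = [f for f in _FIELDS if f not in values]
        if missing:
            raise MassConfigError(
                f"mass config {path} is missing constants: {', '.join(missing)}")
        return cls(name=name, **values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"name = {self.name}"]
        lines += [f"{field} = {getattr(self, field)!r}" for field in _FIELDS]
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict:
        return asdict(self)


def composition_mass(comp: GlycanComposition, cfg: MassConfig) -> float:
    """Theoretical m/z of a composition under a mass configuration.

    Additive in every count: core residues, excess monosaccharides, one
    sialic-acid derivatization per NeuAc/NeuGc, acetyl modifications, the
    completing water, the reducing-end label and the ionization adduct.
    """
    core = comp.core
    mass = (core.hex_count + comp.hex) * cfg.hex
    mass += (core.hexnac_count + comp.hexnac) * cfg.hexnac
    mass += comp.fuc * cfg.fuc
    mass += comp.neuac * (cfg.neuac + cfg.sialic_derivatization)
    mass += comp.neugc * (cfg.neugc + cfg.sialic_derivatization)
    mass += comp.acetyl * cfg.acetyl
    mass += cfg.water + cfg.label + cfg.adduct
    return mass


#: Composition of the A2GN1 internal standard: a disialylated biantennary
#: glycan on the single-GlcNAc core, spiked at known pmol for quantification.
A2GN1_COMPOSITION = GlycanComposition(
    core=Core.N1, hex=2, hexnac=2, neuac=2)


def a2gn1_mz(cfg: MassConfig | None = None) -> float:
    """Theoretical m/z of the A2GN1 internal standard under ``cfg``."""
    return composition_mass(A2GN1_COMPOSITION, cfg or MassConfig.default())
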