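"""Elemental formulas and monoisotopic masses for glycan building blocks.

All residue masses used by the package are derived at import time from
elemental formulas and CODATA/IUPAC monoisotopic atomic masses, so the
provenance of every constant is auditable from this file alone.
"""

from __future__ import annotations

from collections import Counter

# Monoisotopic atomic masses (Da), IUPAC 2021 values.
ATOMIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

#: Mass of a proton (Da) — the default ionization adduct for [M+H]+ species.
PROTON_MASS = 1.007276466812


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-style formula such as ``"C6H10O5"`` into element counts."""
    counts: Counter = Counter()
    i = 0
    while i < len(formula):
        ch = formula[i]
        if not ch.isalpha() or not ch.isupper():
            raise ValueError(f"malformed formula {formula!r} at position {i}")
        j = i + 1
        while j < len(formula) and formula[j].islower():
            j += 1
        elem = formula[i:j]
        i = j
        while j < len(formula) and formula[j].isdigit():
            j += 1
        counts[elem] += int(formula[i:j] or 1)
        i = j
    return counts


def monoisotopic_mass(formula: str | Counter) -> float:
    """Monoisotopic mass (Da) of an elemental formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - configuration error path
        raise KeyError(f"no atomic mass for element {exc}") from None


# Glycan residue formulas (dehydrated, i.e. as incorporated in the chain).
RESIDUE_FORMULA = {
    "hex": "C6H10O5",      # Man / Gal / Glc
    "hexnac": "C8H13NO5",  # GlcNAc / GalNAc
    "fuc": "C6H10O4",      # deoxyhexose
    "neuac": "C11H17NO8",  # N-acetylneuraminic acid
    "neugc": "C11H17NO9",  # N-glycolylneuraminic acid
}

#: Net increments for derivatizations and modifications.
INCREMENT_FORMULA = {
    "water": "H2O",          # completes the free reducing-end glycan
    "methyl_ester": "CH2",   # methyl esterification of a carboxylic acid
    "acetyl": "C2H2O",       # O-acetylation
}

# aoWR: aminooxy-acetyl tryptophanyl-arginine, the reducing-end label used
# for glycoblotting-based MALDI detection.  Oxime formation with the reducing
# sugar is a condensation, so the net label increment is aoWR - H2O.
AOWR_FORMULA = "C19H26N6O5"


def residue_mass(name: str) -> float:
    """Monoisotopic mass of a dehydrated residue by class name."""
    return monoisotopic_mass(RESIDUE_FORMULA[name])
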