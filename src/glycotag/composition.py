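"""Glycan compositions, core codes and the five-digit notation.

A composition counts monosaccharides *in excess of* a named core:

* ``C``  — the Man3GlcNAc2 core of protein-linked N-glycans,
* ``N2`` — the same Man3GlcNAc2 core on a free N-glycan,
* ``N1`` — the Man3GlcNAc1 core of ENGase-processed free N-glycans.

The five digits count Hex, HexNAc, Fuc, NeuAc and NeuGc.  Pauci-mannose
structures smaller than the trimannosyl core (Man1-2GlcNAc2) are written with
a signed Hex digit, e.g. ``-20000`` — a minimal extension of the notation;
all other digits are 0-9.  O-acetyl groups are not part of the five digits
and are rendered as a ``+nAc`` suffix.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace


class Core(str, enum.Enum):
    """Reducing-end core of a glycan."""

    C = "C"      # Man3GlcNAc2, protein-linked N-glycan
    N2 = "N2"    # Man3GlcNAc2, free N-glycan
    N1 = "N1"    # Man3GlcNAc1, free N-glycan (ENGase product)

    @property
    def hex_count(self) -> int:
        return 3

    @property
    def hexnac_count(self) -> int:
        return 1 if self is Core.N1 else 2

    @property
    def has_core_fucose_site(self) -> bool:
        """Whether the reducing-end GlcNAc carrying core fucose is present.

        ENGase cleaves the chitobiose unit and removes the reducing GlcNAc,
        so N1-core glycans cannot be core-fucosylated.
        """
        return self is not Core.N1


class NotationError(ValueError):
    """Raised for compositions or strings the five-digit notation cannot carry."""


_NOTATION_RE = re.compile(
    r"^(?P<hex>-?\d)(?P<hexnac>\d)(?P<fuc>\d)(?P<neuac>\d)(?P<neugc>\d)"
    r"(?:\+(?P<ac>\d)Ac)?$"
)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts in excess of ``core`` plus modifications.

    ``hex`` may be negative (>= -2) for pauci-mannose glycans in which core
    mannoses have been trimmed; all other counts are non-negative.
    """

    core: Core
    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0
    acetyl: int = 0

    def __post_init__(self) -> None:
        if self.hex < -2:
            raise ValueError(f"hex count {self.hex} below -2 (core has 3 Man)")
        for field in ("hexnac", "fuc", "neuac", "neugc", "acetyl"):
            if getattr(self, field) < 0:
                raise ValueError(f"negative {field} count")

    @property
    def sialic(self) -> int:
        return self.neuac + self.neugc

    def add(self, **deltas: int) -> "GlycanComposition":
        """A copy with counts incremented, e.g. ``comp.add(hex=1)``."""
        return replace(self, **{k: getattr(self, k) + v for k, v in deltas.items()})

    def __str__(self) -> str:  # canonical text form, e.g. "C:21020+1Ac"
        return f"{self.core.value}:{to_five_digit(self)}"


def to_five_digit(comp: GlycanComposition) -> str:
    """Render the five-digit notation (without the core code).

    Counts above 9 are unrepresentable in one digit each and raise
    :class:`NotationError`.  A trimmed-core Hex count (-1 or -2, pauci-mannose
    only) is rendered with a leading minus sign.  Acetyl groups, which have no
    digit of their own, appear as a ``+nAc`` suffix.
    """
    digits = (comp.hex, comp.hexnac, comp.fuc, comp.neuac, comp.neugc)
    for value in digits:
        if value > 9:
            raise NotationError(f"count {value} exceeds one digit in {comp!r}")
    text = "".join(str(d) for d in digits)
    if comp.acetyl:
        if comp.acetyl > 9:
            raise NotationError(f"acetyl count {comp.acetyl} exceeds one digit")
        text += f"+{comp.acetyl}Ac"
    return text


def parse_five_digit(text: str, core: Core | str) -> GlycanComposition:
    """Inverse of :func:`to_five_digit`.

    ``text`` is five decimal digits (the Hex digit may carry a leading minus
    for trimmed pauci-mannose cores) with an optional ``+nAc`` suffix.
    """
    core = Core(core)
    m = _NOTATION_RE.match(text.strip())
    if m is None:
        for pos, ch in enumerate(text):
            if not (ch.isdigit() or ch in "-+Ac"):
                raise NotationError(f"malformed notation {text!r} at position {pos}")
        raise NotationError(f"malformed notation {text!r}")
    return GlycanComposition(
        core=core,
        hex=int(m.group("hex")),
        hexnac=int(m.group("hexnac")),
        fuc=int(m.group("fuc")),
        neuac=int(m.group("neuac")),
        neugc=int(m.group("neugc")),
        acetyl=int(m.group("ac") or 0),
    )


def parse_composition(text: str) -> GlycanComposition:
    """Parse the canonical ``core:digits`` form produced by ``str(comp)``."""
    try:
        core_text, digits = text.split(":", 1)
    except ValueError:
        raise NotationError(f"expected 'CORE:digits', got {text!r}") from None
    return parse_five_digit(digits, core_text)
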