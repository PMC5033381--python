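"""Monosaccharide identities and the built-in residue catalog.

Residues are modelled at the level the elucidation logic needs: a name
token (``Glc``, ``GalA``, ``6dTal`` ... or a generic class token such as
``Hex``), a sugar class (hexose, 6-deoxyhexose, hexuronic acid), and
optional absolute (D/L) and anomeric (alpha/beta) configuration.  All
sugars handled here are aldopyranoses, so the anomeric carbon is always
ring position 1 and the ring oxygen sits on C-5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum


class SugarClass(str, Enum):
    HEX = "Hex"
    DHEX = "dHex"
    HEXA = "HexA"


#: Elemental formula of the anhydro (glycosidically bound) residue.
ANHYDRO_FORMULA: dict[SugarClass, dict[str, int]] = {
    SugarClass.HEX: {"C": 6, "H": 10, "O": 5},
    SugarClass.DHEX: {"C": 6, "H": 10, "O": 4},
    SugarClass.HEXA: {"C": 6, "H": 8, "O": 6},
}

#: Ring positions carrying a free hydroxyl on an otherwise unsubstituted
#: internal residue (anomeric O is part of the glycosidic bond, position 5
#: is the ring oxygen; 6-deoxy sugars lack the 6-OH; uronic acids carry a
#: carboxyl at C-6 instead of a hydroxymethyl group).
HYDROXYL_POSITIONS: dict[SugarClass, frozenset[int]] = {
    SugarClass.HEX: frozenset({2, 3, 4, 6}),
    SugarClass.DHEX: frozenset({2, 3, 4}),
    SugarClass.HEXA: frozenset({2, 3, 4}),
}

#: name -> sugar class.  Generic class tokens are valid residue names so
#: that observations can be stated at class level only.
CATALOG: dict[str, SugarClass] = {
    "Glc": SugarClass.HEX,
    "Gal": SugarClass.HEX,
    "Man": SugarClass.HEX,
    "All": SugarClass.HEX,
    "Alt": SugarClass.HEX,
    "Gul": SugarClass.HEX,
    "Ido": SugarClass.HEX,
    "Tal": SugarClass.HEX,
    "Fuc": SugarClass.DHEX,
    "Rha": SugarClass.DHEX,
    "Qui": SugarClass.DHEX,
    "6dTal": SugarClass.DHEX,
    "6dGul": SugarClass.DHEX,
    "GlcA": SugarClass.HEXA,
    "GalA": SugarClass.HEXA,
    "IdoA": SugarClass.HEXA,
    "ManA": SugarClass.HEXA,
    "Hex": SugarClass.HEX,
    "dHex": SugarClass.DHEX,
    "HexA": SugarClass.HEXA,
}

CLASS_TOKENS = frozenset({"Hex", "dHex", "HexA"})


def sugar_class_of(name: str) -> SugarClass:
    """Sugar class of a catalog name or generic class token."""
    try:
        return CATALOG[name]
    except KeyError:
        raise KeyError(f"unknown sugar token {name!r}; known: {sorted(CATALOG)}") from None


def is_class_token(name: str) -> bool:
    return name in CLASS_TOKENS


@dataclass(frozen=True)
class MonosaccharideIdentity:
    """A named sugar with optional configuration attributes.

    ``absolute_config`` and ``anomeric_config`` default to ``"unknown"``;
    the topology solver works at name/class level and treats the
    configuration attributes as optional refinements.  ``o_acetyl`` stores
    known O-acetylation sites; the elucidation pipeline never infers it.
    """

    name: str
    absolute_config: str = "unknown"   # "D" | "L" | "unknown"
    anomeric_config: str = "unknown"   # "alpha" | "beta" | "unknown"
    ring: str = "p"                    # pyranose only; "f" rejected by default
    o_acetyl: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sugar_class_of(self.name)  # validates the token
        if self.absolute_config not in ("D", "L", "unknown"):
            raise ValueError(f"bad absolute config {self.absolute_config!r}")
        if self.anomeric_config not in ("alpha", "beta", "unknown"):
            raise ValueError(f"bad anomeric config {self.anomeric_config!r}")
        if self.ring != "p":
            raise ValueError("only pyranose residues are supported")

    @property
    def sugar_class(self) -> SugarClass:
        return sugar_class_of(self.name)

    @property
    def anhydro_formula(self) -> Counter:
        return Counter(ANHYDRO_FORMULA[self.sugar_class])

    @property
    def hydroxyl_positions(self) -> frozenset[int]:
        return HYDROXYL_POSITIONS[self.sugar_class]

    def token(self, level: str = "full") -> str:
        """Condensed-notation token, e.g. ``α-D-Galp`` or ``β-D-GlcpA``.

        ``level`` controls how much identity detail is rendered:
        ``"full"`` (configurations when known), ``"name"`` (name only) or
        ``"class"`` (generic class token).
        """
        if level == "class":
            return self.sugar_class.value
        name = self.name
        ring_name = name[:-1] + "p" + "A" if name.endswith("A") and name != "HexA" else name + "p"
        if name == "HexA":
            ring_name = "HexpA"
        if level == "name":
            return ring_name
        parts = []
        if self.anomeric_config != "unknown":
            parts.append({"alpha": "α", "beta": "β"}[self.anomeric_config])
        if self.absolute_config != "unknown":
            parts.append(self.absolute_config)
        parts.append(ring_name)
        return "-".join(parts)

    def strip_attrs(self) -> "MonosaccharideIdentity":
        """Identity reduced to its name (configurations dropped)."""
        return MonosaccharideIdentity(self.name)

    def with_config(self, absolute: str | None = None, anomeric: str | None = None) -> "MonosaccharideIdentity":
        out = self
        if absolute is not None:
            out = replace(out, absolute_config=absolute)
        if anomeric is not None:
            out = replace(out, anomeric_config=anomeric)
        return out


def identities_match(a: str, b: str) -> bool:
    """Name/class compatibility used throughout the solver.

    Two sugar tokens are compatible when their names agree, or when at
    least one of them is a generic class token and the classes agree.
    """
    if a == b:
        return True
    if is_class_token(a) or is_class_token(b):
        return sugar_class_of(a) == sugar_class_of(b)
    return False
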