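"""Exact mass arithmetic for native and derivatized glycans and their
fragment ions.

Masses are computed from element-count formulas using IUPAC monoisotopic
atomic masses (hard-coded below); average masses are provided for the
polymer-repeat molar mass needed by the optical-rotation module.
Ionization adds the mass of a proton (1.007276 Da, i.e. an H atom minus
an electron); non-protonating adducts likewise account for the electron.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .residues import MonosaccharideIdentity, SugarClass
from .tree import GlycanTree, RepeatUnit

MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.007825,
    "D": 2.014102,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "Si": 27.976927,
    "Na": 22.989770,
    "K": 38.963707,
}

AVERAGE = {
    "C": 12.011,
    "H": 1.008,
    "D": 2.014,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Si": 28.085,
    "Na": 22.990,
    "K": 39.098,
}

ELECTRON = 0.000549
PROTON = MONOISOTOPIC["H"] - ELECTRON  # 1.007276 Da

WATER = Counter({"H": 2, "O": 1})
CH2 = Counter({"C": 1, "H": 2})                 # net methylation delta (O-H -> O-CH3)
CD3_MINUS_H = Counter({"C": 1, "D": 3, "H": -1})
TMS = Counter({"C": 3, "H": 8, "Si": 1})        # net trimethylsilylation delta

#: formula added by each adduct species (charge is carried by electron loss)
ADDUCT_FORMULA = {
    "+H": Counter({"H": 1}),
    "+Na": Counter({"Na": 1}),
    "+K": Counter({"K": 1}),
    "+NH4": Counter({"N": 1, "H": 4}),
}


def formula_mass(formula: Counter, average: bool = False) -> float:
    table = AVERAGE if average else MONOISOTOPIC
    return sum(table[el] * n for el, n in formula.items())


def formula_to_string(formula: Counter) -> str:
    order = ["C", "H", "D", "N", "O", "S", "Si", "Na", "K"]
    return "".join(
        f"{el}{formula[el]}" if formula[el] != 1 else el
        for el in order
        if formula.get(el)
    )


class Methylation(str, Enum):
    NONE = "none"
    CH3 = "CH3"
    CD3 = "CD3"


class Reduction(str, Enum):
    NONE = "none"
    BH4 = "BH4"
    BD4 = "BD4"


@dataclass(frozen=True)
class DerivatizationScheme:
    """How hydroxyls, the anomeric centre and the charge state are handled.

    ``condensation_partner`` is an element-count map for a reagent that
    condenses with the (free) reducing end; ``condensation_water_loss``
    subtracts one water for the condensation (e.g. thiazolidine formation
    with L-cysteine methyl ester).  ``silylation_count`` is the total
    number of trimethylsilyl groups installed.
    """

    methylation: Methylation = Methylation.NONE
    reduction: Reduction = Reduction.NONE
    silylation_count: int = 0
    condensation_partner: dict[str, int] | None = None
    condensation_water_loss: bool = True
    adduct: str = "none"     # none | +H | +Na | +K | +NH4
    charge: int = 1

    def __post_init__(self) -> None:
        if self.adduct != "none" and self.adduct not in ADDUCT_FORMULA:
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if self.adduct != "none" and self.charge < 1:
            raise ValueError("charge must be >= 1 for an ionized species")
        if self.silylation_count < 0:
            raise ValueError("silylation count must be >= 0")
        if self.methylation != Methylation.NONE and self.silylation_count:
            raise ValueError("methylation and silylation are mutually exclusive")
        if self.reduction != Reduction.NONE and self.condensation_partner is not None:
            raise ValueError("reduction and anomeric condensation are mutually exclusive")

    @property
    def methyl_delta(self) -> Counter | None:
        if self.methylation == Methylation.CH3:
            return CH2
        if self.methylation == Methylation.CD3:
            return CD3_MINUS_H
        return None


NATIVE = DerivatizationScheme()

#: L-cysteine methyl ester, the chiral derivatization reagent used for
#: GC-MS D/L discrimination of neutral sugars (condenses with loss of water).
CYSTEINE_METHYL_ESTER = {"C": 4, "H": 9, "N": 1, "O": 2, "S": 1}


@dataclass(frozen=True)
class IonMass:
    """A neutral (and optionally ionized) species with its formula."""

    neutral_mass: float
    formula: Counter = field(default_factory=Counter)
    mz: float | None = None
    charge: int = 1
    adduct: str = "none"


def _apply_adduct(neutral: float, formula: Counter, scheme: DerivatizationScheme) -> IonMass:
    if scheme.adduct == "none":
        return IonMass(neutral_mass=neutral, formula=formula)
    z = scheme.charge
    adduct_formula = Counter()
    for _ in range(z):
        adduct_formula += ADDUCT_FORMULA[scheme.adduct]
    mz = (neutral + formula_mass(adduct_formula) - z * ELECTRON) / z
    return IonMass(neutral_mass=neutral, formula=formula, mz=mz, charge=z, adduct=scheme.adduct)


def _methyl_sites_internal(ident: MonosaccharideIdentity, substituted: frozenset[int]) -> int:
    """Free hydroxyls of a glycosidically bound residue; permethylation
    additionally esterifies a uronic carboxyl (counted as one site)."""
    sites = len(ident.hydroxyl_positions - substituted)
    if ident.sugar_class == SugarClass.HEXA:
        sites += 1  # COOH -> COOCH3
    return sites


def residue_mass(
    identity: MonosaccharideIdentity,
    scheme: DerivatizationScheme = NATIVE,
    free_positions: int | None = None,
) -> float:
    """Monoisotopic mass of the anhydro residue under ``scheme``.

    ``free_positions`` is the number of underivatized hydroxyls left free
    by linkages (defaults to all of them); with methylation each free
    position carries a methyl group, and uronic residues additionally
    carry a carboxyl methyl ester.
    """
    if free_positions is None:
        free_positions = len(identity.hydroxyl_positions)
    if free_positions < 0:
        raise ValueError("free_positions must be >= 0")
    formula = identity.anhydro_formula
    delta = scheme.methyl_delta
    if delta is not None:
        n = free_positions + (1 if identity.sugar_class == SugarClass.HEXA else 0)
        for _ in range(n):
            formula += delta
    return formula_mass(formula)


def _tree_formula(tree: GlycanTree, scheme: DerivatizationScheme) -> Counter:
    formula = Counter()
    for ident in tree.residues.values():
        formula += ident.anhydro_formula
    formula += WATER  # free reducing end
    if scheme.reduction == Reduction.BH4:
        formula += Counter({"H": 2})
    elif scheme.reduction == Reduction.BD4:
        formula += Counter({"H": 1, "D": 1})
    if scheme.condensation_partner is not None:
        formula += Counter(scheme.condensation_partner)
        if scheme.condensation_water_loss:
            formula -= WATER
    delta = scheme.methyl_delta
    if delta is not None:
        for _ in range(_methyl_site_count(tree, scheme)):
            formula += delta
    for _ in range(scheme.silylation_count):
        formula += TMS
    return Counter({el: n for el, n in formula.items() if n})


def _methyl_site_count(tree: GlycanTree, scheme: DerivatizationScheme) -> int:
    """Methylatable sites of a whole (free) glycan: free ring hydroxyls,
    uronic carboxyls, the anomeric hydroxyl of an unreduced reducing end,
    or the two extra alditol hydroxyls (O-1, O-5) after reduction."""
    sites = 0
    for rid, ident in tree.residues.items():
        sites += _methyl_sites_internal(ident, tree.substituted_positions(rid))
    sites += 2 if scheme.reduction != Reduction.NONE else 1
    if scheme.condensation_partner is not None:
        sites -= 1  # anomeric centre consumed by the condensation
    return sites


def glycan_mass(
    structure: GlycanTree | RepeatUnit, scheme: DerivatizationScheme = NATIVE
) -> IonMass:
    """Neutral mass (and m/z when an adduct is set) of a released glycan.

    A :class:`RepeatUnit` is measured as one released unit, i.e. with a
    free reducing end, identical to its underlying tree.
    """
    tree = structure.tree if isinstance(structure, RepeatUnit) else structure
    formula = _tree_formula(tree, scheme)
    return _apply_adduct(formula_mass(formula), formula, scheme)


def unit_average_mass(structure: GlycanTree | RepeatUnit) -> float:
    """Average molar mass of one polymer repeat: anhydro residues summed,
    no terminal water (polymer-repeat convention)."""
    tree = structure.tree if isinstance(structure, RepeatUnit) else structure
    formula = Counter()
    for ident in tree.residues.values():
        formula += ident.anhydro_formula
    return formula_mass(formula, average=True)


def derivative_mz(
    identity: MonosaccharideIdentity, scheme: DerivatizationScheme
) -> IonMass:
    """m/z of a derivatized *free* monosaccharide.

    Covers condensation derivatives such as the trimethylsilylated
    L-cysteine methyl ester adducts used for D/L assignment of neutral
    sugars by GC-MS.
    """
    formula = identity.anhydro_formula + WATER
    available = len(identity.hydroxyl_positions) + (
        1 if identity.sugar_class == SugarClass.HEXA else 0
    )
    if scheme.condensation_partner is not None:
        formula += Counter(scheme.condensation_partner)
        if scheme.condensation_water_loss:
            formula -= WATER
        available += 2  # ring-opened OH and the partner's N-H
    else:
        available += 1  # anomeric hydroxyl
    if scheme.reduction == Reduction.BH4:
        formula += Counter({"H": 2})
    elif scheme.reduction == Reduction.BD4:
        formula += Counter({"H": 1, "D": 1})
    if scheme.silylation_count > available:
        raise ValueError(
            f"silylation count {scheme.silylation_count} exceeds the "
            f"{available} exchangeable hydrogens of this derivative"
        )
    for _ in range(scheme.silylation_count):
        formula += TMS
    delta = scheme.methyl_delta
    if delta is not None:
        n = available if scheme.condensation_partner is None else available - 2
        for _ in range(n):
            formula += delta
    return _apply_adduct(formula_mass(formula), formula, scheme)


# ---------------------------------------------------------------------------
# fragment ions
# ---------------------------------------------------------------------------

#: Default mass delta of a 1,5X ion over the y ion at the same glycosidic
#: bond: the retained C-1/O-5 ring remnant, i.e. +CO by homolytic atom
#: partition.  Configurable because published spectra rarely state the
#: convention.
X15_DELTA = formula_mass(Counter({"C": 1, "O": 1}))  # 27.994915 Da


@dataclass(frozen=True)
class FragmentIon:
    label: str              # e.g. "b2", "y3", "x15_3"
    ion_type: str           # "b" | "y" | "x15"
    cleaved_edge: tuple[str, str, int]
    neutral_mass: float
    mz: float | None
    residue_count: int


def fragment_ion_mzs(
    tree: GlycanTree,
    scheme: DerivatizationScheme = NATIVE,
    ion_types: frozenset[str] | set[str] = frozenset({"b", "y", "x15"}),
    x15_delta: float = X15_DELTA,
) -> list[FragmentIon]:
    """Single-cleavage glycosidic fragment ions for every edge of ``tree``.

    For the cleavage of edge ``child -(1→p)- parent``:

    * ``b``: the non-reducing piece (the subtree under ``child``); its
      neutral mass is the sum of its anhydro residues (the oxocarbenium
      equivalent), derivatized per ``scheme``.
    * ``y``: the reducing piece, with the glycosidic oxygen retained and
      protonated (a free hydroxyl at the cleavage position, which stays
      unmethylated under permethylation schemes); reduction and
      condensation deltas apply to this piece.
    * ``x15``: the y mass plus ``x15_delta`` (see :data:`X15_DELTA`).

    b-neutral + y-neutral equals the full glycan neutral mass exactly.
    """
    unknown = set(ion_types) - {"b", "y", "x15"}
    if unknown:
        raise ValueError(f"unknown ion types {sorted(unknown)}")
    ions: list[FragmentIon] = []
    for child, parent, pos in tree.edges():
        piece_ids = tree.subtree_ids(child)
        rest_ids = set(tree.residues) - piece_ids
        # b piece: anhydro residues with their free hydroxyls derivatized
        b_formula = Counter()
        for rid in piece_ids:
            b_formula += tree.residues[rid].anhydro_formula
        delta = scheme.methyl_delta
        if delta is not None:
            for rid in piece_ids:
                n = _methyl_sites_internal(
                    tree.residues[rid], tree.substituted_positions(rid)
                )
                for _ in range(n):
                    b_formula += delta
        b_neutral = formula_mass(b_formula)
        # y piece: the remainder of the whole-glycan formula
        full = _tree_formula(tree, scheme)
        y_formula = full - b_formula
        y_neutral = formula_mass(y_formula)
        nb, ny = len(piece_ids), len(rest_ids)
        if "b" in ion_types:
            ion = _apply_adduct(b_neutral, b_formula, scheme)
            ions.append(FragmentIon(f"b{nb}", "b", (child, parent, pos), b_neutral, ion.mz, nb))
        if "y" in ion_types:
            ion = _apply_adduct(y_neutral, y_formula, scheme)
            ions.append(FragmentIon(f"y{ny}", "y", (child, parent, pos), y_neutral, ion.mz, ny))
        if "x15" in ion_types:
            x_neutral = y_neutral + x15_delta
            ion = _apply_adduct(x_neutral, y_formula, scheme)
            ions.append(
                FragmentIon(f"x15_{ny}", "x15", (child, parent, pos), x_neutral, ion.mz, ny)
            )
    ions.sort(key=lambda f: (f.ion_type, f.residue_count, f.cleaved_edge))
    return ions


def match_mz(observed: float, theoretical: float, tolerance: float = 0.01) -> bool:
    """Default m/z matching window (Da), configurable per call."""
    return abs(observed - theoretical) <= tolerance
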