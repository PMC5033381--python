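"""Additive molar-rotation arithmetic for D/L configuration assignment.

By Hudson's isorotation rules the molar rotation [M]_D of an
oligosaccharide is approximately the sum of the molar rotations of its
constituent glycosides (methyl pyranoside convention).  Because the two
enantiomers of a residue contribute values of opposite sign, comparing
the calculated specific rotation of the candidate D- and L-containing
structures against the measured value discriminates the absolute
configuration of a single doubtful residue — here the 6-deoxy-talose of
a hexasaccharide repeat unit.

The specific rotation follows as ``[α]_D = 100 × [M]_D / M`` with ``M``
the *average* molar mass of one anhydro repeat unit (no terminal water,
the polymer-repeat convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .masses import unit_average_mass
from .residues import MonosaccharideIdentity
from .tree import GlycanTree, RepeatUnit


class MissingRotationConstant(KeyError):
    pass


@dataclass(frozen=True)
class RotationEntry:
    name: str
    anomeric: str           # "alpha" | "beta"
    absolute: str           # "D" | "L"
    molar_rotation: float   # deg·cm²·dag⁻¹, methyl pyranoside convention
    source: str = ""


class RotationConstants:
    """Lookup table (name, anomeric, absolute) → molar-rotation contribution."""

    def __init__(self, entries: list[RotationEntry]):
        self._table = {(e.name, e.anomeric, e.absolute): e for e in entries}

    @classmethod
    def from_yaml(cls, path=None) -> "RotationConstants":
        if path is None:
            ref = resources.files("glycoelucidate.data") / "rotation_constants.yaml"
            text = ref.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
        entries = [
            RotationEntry(
                name=e["residue"],
                anomeric=e["anomeric"],
                absolute=e["absolute"],
                molar_rotation=float(e["molar_rotation"]),
                source=e.get("source", ""),
            )
            for e in raw
        ]
        return cls(entries)

    def lookup(self, ident: MonosaccharideIdentity) -> RotationEntry:
        key = (ident.name, ident.anomeric_config, ident.absolute_config)
        try:
            return self._table[key]
        except KeyError:
            raise MissingRotationConstant(
                f"no molar-rotation constant for {ident.token()} "
                f"(need name/anomeric/absolute = {key})"
            ) from None

    def __contains__(self, key) -> bool:
        return key in self._table


_default_constants: RotationConstants | None = None


def default_constants() -> RotationConstants:
    global _default_constants
    if _default_constants is None:
        _default_constants = RotationConstants.from_yaml()
    return _default_constants


def molar_rotation(
    structure: RepeatUnit | GlycanTree, constants: RotationConstants | None = None
) -> float:
    """Sum of per-residue molar-rotation contributions (pure additivity).

    Raises :class:`MissingRotationConstant` naming the first residue that
    cannot be resolved in the table.
    """
    if constants is None:
        constants = default_constants()
    tree = structure.tree if isinstance(structure, RepeatUnit) else structure
    return sum(constants.lookup(ident).molar_rotation for _, ident in sorted(tree.residues.items()))


def specific_rotation(molar_rotation_value: float, unit_molar_mass: float) -> float:
    """[α]_D = 100 × [M]_D / M for a repeat of average molar mass ``M``."""
    if unit_molar_mass <= 0:
        raise ValueError("unit molar mass must be positive")
    return 100.0 * molar_rotation_value / unit_molar_mass


@dataclass(frozen=True)
class ConfigurationAssignment:
    label: str              # winning candidate, or "indeterminate" on a tie
    margin: float           # |runner-up error| − |winner error|
    predictions: dict[str, float]


def assign_configuration(
    measured: float,
    candidates: dict[str, float],
    precision: float = 0.5,
) -> ConfigurationAssignment:
    """Pick the candidate whose predicted rotation is closest to the
    measured one; a tie within ``precision`` degrees is reported as
    ``indeterminate`` rather than silently broken."""
    if len(candidates) < 2:
        raise ValueError("configuration assignment needs at least two candidates")
    errors = sorted((abs(measured - v), k) for k, v in candidates.items())
    margin = errors[1][0] - errors[0][0]
    label = errors[0][1] if margin > precision else "indeterminate"
    return ConfigurationAssignment(label=label, margin=margin, predictions=dict(candidates))


def rotation_report(
    unit: RepeatUnit | GlycanTree,
    variants: dict[str, RepeatUnit | GlycanTree],
    measured: float,
    constants: RotationConstants | None = None,
) -> dict:
    """Convenience: compute [M]_D and [α]_D for each structural variant and
    assign the configuration against ``measured``."""
    mass = unit_average_mass(unit)
    preds: dict[str, float] = {}
    details: dict[str, dict] = {}
    for label, variant in variants.items():
        md = molar_rotation(variant, constants)
        alpha = specific_rotation(md, mass)
        preds[label] = alpha
        details[label] = {"molar_rotation": md, "specific_rotation": alpha}
    call = assign_configuration(measured, preds)
    return {
        "unit_molar_mass": mass,
        "measured": measured,
        "variants": details,
        "assignment": call,
    }
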