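"""Packaged reference data: the B. longum 35624 exopolysaccharide repeat
unit, its published observation set, NMR assignments and HMBC
correlations.

The exopolysaccharide of *Bifidobacterium longum* subsp. *longum* 35624
is built from a branched hexasaccharide repeating unit::

    →4)-β-D-Glcp-(1→4)-α-L-6dTalp-(1→4)-α-D-GalpA-(1→4)-α-D-Galp-(1→4)-
        [α-D-Glcp-(1→2)]-α-D-Galp-(1→

with residue labels A–F as used in the NMR assignment table: A the
4-substituted β-glucose, B the 4-substituted 6-deoxy-L-talose, C the
4-substituted galacturonic acid, D the 4-substituted α-galactose, E the
2,4-disubstituted α-galactose whose anomeric bond chains the units, and
F the terminal α-glucose branch.
"""

from __future__ import annotations

from importlib import resources

from .elucidate import ObservationSet
from .io import load_observations
from .nmr import HMBCCorrelation, NMRTable
from .tree import RepeatUnit, parse_condensed


def _data(name: str):
    return resources.files("glycoelucidate.data") / name


def eps35624_structure_string() -> str:
    return _data("eps35624_structure.txt").read_text().strip()


def eps35624_repeat_unit() -> RepeatUnit:
    """The published hexasaccharide repeat unit as a :class:`RepeatUnit`."""
    unit = parse_condensed(eps35624_structure_string())
    assert isinstance(unit, RepeatUnit)
    return unit


def eps35624_labels() -> dict[str, str]:
    """NMR residue labels (A–F) → residue ids of the parsed repeat unit.

    Parse order of the packaged condensed string: main chain A, B, C, D,
    then the bracketed branch F, then the chain-terminating E.
    """
    return {"A": "r0", "B": "r1", "C": "r2", "D": "r3", "F": "r4", "E": "r5"}


def eps35624_observations() -> ObservationSet:
    """The study's combined evidence set: sugar composition (2:2:1:1
    Glc:Gal:GalA:6dTal), the PMAA linkage multiset (galacturonic acid
    flagged undetectable), the os211/os311a/os411a/os411b hydrolysis
    fragments, the aldobiuronic HexA→Hex adjacency and the four
    inter-residue HMBC bonds."""
    with resources.as_file(_data("eps35624_observations.json")) as path:
        return load_observations(path)


def eps35624_nmr_table() -> NMRTable:
    """Assigned ¹H/¹³C chemical shifts of the exopolysaccharide."""
    return NMRTable.from_csv()


def eps35624_hmbc_correlations() -> list[HMBCCorrelation]:
    """The four observed inter-residue HMBC correlations: H-1(A)→C-4(B),
    H-1(B)→C-4(C), H-4(E)→C-1(D) and H-1(F)→C-2(E)."""
    return [
        HMBCCorrelation("A", 1, "B", 4),
        HMBCCorrelation("B", 1, "C", 4),
        HMBCCorrelation("E", 4, "D", 1),
        HMBCCorrelation("F", 1, "E", 2),
    ]
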