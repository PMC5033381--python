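"""Exhaustive enumeration of acid-hydrolysis fragments of the repeating
polymer.

Partial acid hydrolysis is modelled as cleavage of an arbitrary subset of
glycosidic bonds, without kinetic weighting: every connected subtree of
the (conceptually infinite) chained polymer is a possible fragment.  The
residue of a fragment closest to the polymer's reducing end is the one
whose anomeric bond was cleaved, hence the fragment's reducing end.
Fragments are deduplicated structurally (canonical form), because mass
spectrometry cannot distinguish translated copies along the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .residues import SugarClass, sugar_class_of
from .tree import Composition, GlycanTree, RepeatUnit


@dataclass(frozen=True)
class FragmentStructure:
    """A hydrolysis fragment: a glycan tree plus its canonical key."""

    tree: GlycanTree
    canonical: str

    @property
    def reducing_end(self) -> str:
        return self.tree.residues[self.tree.root_id].name

    @property
    def reducing_end_class(self) -> SugarClass:
        return self.tree.residues[self.tree.root_id].sugar_class

    def composition(self, level: str = "name") -> Composition:
        return self.tree.composition(level)


def reducing_end_class(frag: FragmentStructure | GlycanTree) -> SugarClass:
    tree = frag.tree if isinstance(frag, FragmentStructure) else frag
    return tree.residues[tree.root_id].sugar_class


def _rooted_subtrees(tree: GlycanTree, top: str, size: int):
    """Yield all connected id-sets of ``size`` residues whose topmost
    (reducing) residue is ``top``.

    Standard rooted-subgraph enumeration: grow the set along an ordered
    extension list so each subtree is produced exactly once.
    """
    children = {rid: [c for c, _ in tree.children(rid)] for rid in tree.residues}

    def grow(selected: list[str], ext: list[str]):
        if len(selected) == size:
            yield set(selected)
            return
        for i, nxt in enumerate(ext):
            yield from grow(selected + [nxt], ext[i + 1:] + children[nxt])

    yield from grow([top], children[top])


def min_window(unit: RepeatUnit, size: int) -> int:
    """Number of chained copies guaranteed to contain every translated
    fragment class of ``size`` residues fully internally.

    A fragment's main-chain extent can cross one backbone period per
    backbone residue it contains, so the bound uses the backbone cycle
    length (not the unit size — side chains shorten the period)."""
    return math.ceil(size / unit.backbone_length) + 2


def enumerate_fragments(
    unit: RepeatUnit,
    size: int,
    composition_filter: Composition | dict | None = None,
    reducing_class: SugarClass | str | None = None,
    window: int | None = None,
) -> list[FragmentStructure]:
    """All distinct connected ``size``-residue fragments of the polymer.

    Results are deduplicated across chain translation by canonical form
    and optionally filtered by composition (name- or class-level counts)
    and by the sugar class of the reducing-end residue.  Returned sorted
    by canonical string for determinism.
    """
    if size < 1:
        raise ValueError("fragment size must be >= 1")
    if window is None:
        window = min_window(unit, size)
    if composition_filter is not None and not isinstance(composition_filter, Composition):
        composition_filter = Composition(composition_filter)
    if isinstance(reducing_class, str):
        reducing_class = SugarClass(reducing_class)
    chain = unit.chain(window)
    seen: dict[str, FragmentStructure] = {}
    for top in chain.residues:
        for ids in _rooted_subtrees(chain, top, size):
            frag_tree = chain.induced(ids)
            if reducing_class is not None and reducing_end_class(frag_tree) != reducing_class:
                continue
            if composition_filter is not None and not frag_tree.composition().matches(
                composition_filter
            ):
                continue
            key = frag_tree.canonical_form()
            if key not in seen:
                seen[key] = FragmentStructure(tree=frag_tree, canonical=key)
    return [seen[k] for k in sorted(seen)]


def has_linear_nonreducing_prefix(frag: FragmentStructure, prefix: list[str]) -> bool:
    """Whether some single cleavage of ``frag`` releases a b-type piece
    that is a linear chain whose residues, read from the non-reducing
    terminus, match ``prefix`` (names or class tokens).

    This is how a b-ion sequence read from an MS/MS spectrum (e.g. the
    Hex-dHex disaccharide b2 ion) constrains a fragment's topology.
    """
    from .residues import identities_match

    tree = frag.tree
    want = len(prefix)
    for child, _, _ in tree.edges():
        ids = tree.subtree_ids(child)
        if len(ids) != want:
            continue
        piece = tree.subtree(child)
        # linear chain check: every residue has at most one child
        if any(len(piece.children(rid)) > 1 for rid in piece.residues):
            continue
        order: list[str] = []
        node = piece.root_id  # cut end (closest to the reducing side)
        stack = [node]
        while stack:
            n = stack.pop()
            order.append(piece.residues[n].name)
            stack.extend(c for c, _ in piece.children(n))
        order.reverse()  # non-reducing terminus first
        if all(identities_match(a, b) for a, b in zip(order, prefix)):
            return True
    return False
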