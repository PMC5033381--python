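"""Hydrolysis-fragment enumeration: counts, filters, oracle equivalence."""

import itertools

import pytest

from glycoelucidate import (
    Composition,
    GeneratorParams,
    SugarClass,
    enumerate_fragments,
    parse_condensed,
    random_repeat_unit,
    reducing_end_class,
)
from glycoelucidate.fragments import has_linear_nonreducing_prefix, min_window

SIX_FILTER = {"Hex": 4, "HexA": 1, "dHex": 1}


def test_six_residue_isomers_of_the_polymer(eps_unit):
    """One six-residue fragment has the deoxyhexose at the reducing end
    (it sits in the main chain); several carry a hexose there."""
    dhex = enumerate_fragments(eps_unit, 6, SIX_FILTER, reducing_class="dHex")
    hexr = enumerate_fragments(eps_unit, 6, SIX_FILTER, reducing_class="Hex")
    assert len(dhex) == 1
    assert len(hexr) == 6
    assert reducing_end_class(dhex[0]) == SugarClass.DHEX


def test_filters_never_grow_result(eps_unit):
    unfiltered = enumerate_fragments(eps_unit, 6)
    filtered = enumerate_fragments(eps_unit, 6, SIX_FILTER)
    assert {f.canonical for f in filtered} <= {f.canonical for f in unfiltered}
    for f in filtered:
        assert f.composition().matches(Composition(SIX_FILTER))


def test_linear_periodic_repeat_counts():
    """A linear repeat of three pairwise distinct residues has exactly one
    size-3 fragment per phase."""
    unit = parse_condensed("→3)-Glcp-(1→4)-Galp-(1→2)-Manp-(1→")
    frags = enumerate_fragments(unit, 3)
    assert len(frags) == 3


def test_single_residue_fragments(eps_unit):
    frags = enumerate_fragments(eps_unit, 1)
    # one per distinct residue identity: β-Glc, α-Glc, 2×α-Gal (identical), GalA, 6dTal
    assert len(frags) == 5
    for f in frags:
        assert reducing_end_class(f) == f.tree.residues[f.tree.root_id].sugar_class


def test_translation_invariance(eps_unit):
    w = min_window(eps_unit, 5)
    a = {f.canonical for f in enumerate_fragments(eps_unit, 5, window=w)}
    b = {f.canonical for f in enumerate_fragments(eps_unit, 5, window=w + 1)}
    assert a == b


def _brute_force(unit, size):
    """Independent oracle: materialize the chain and test every vertex
    subset for connectivity."""
    window = min_window(unit, size)
    chain = unit.chain(window)
    undirected = {rid: set() for rid in chain.residues}
    for c, p, _ in chain.edges():
        undirected[c].add(p)
        undirected[p].add(c)
    found = set()
    for combo in itertools.combinations(sorted(chain.residues), size):
        nodes = set(combo)
        seen = {combo[0]}
        stack = [combo[0]]
        while stack:
            for nxt in undirected[stack.pop()] & nodes - seen:
                seen.add(nxt)
                stack.append(nxt)
        if seen == nodes:
            found.add(chain.induced(nodes).canonical_form())
    return found


@pytest.mark.parametrize("seed", [11, 12, 13])
@pytest.mark.parametrize("size", [2, 3, 4])
def test_enumeration_matches_brute_force(seed, size):
    params = GeneratorParams(seed=seed, size_range=(3, 5))
    unit = random_repeat_unit(params)
    fast = {f.canonical for f in enumerate_fragments(unit, size)}
    assert fast == _brute_force(unit, size)


def test_b_prefix_detection(eps_unit):
    frags = enumerate_fragments(eps_unit, 6, SIX_FILTER, reducing_class="Hex")
    with_prefix = [f for f in frags if has_linear_nonreducing_prefix(f, ["Hex", "dHex"])]
    assert with_prefix  # the Glc-6dTal b2 piece exists on some isomer
    assert not any(has_linear_nonreducing_prefix(f, ["HexA", "HexA"]) for f in frags)


def test_window_respects_short_backbone():
    """Side-chain-heavy units have a backbone period shorter than the unit;
    the window must scale with the backbone, not the unit size."""
    unit = parse_condensed("→4)-Glcp-(1→2)-[Galp-(1→4)-Galp-(1→3)]-Rhap-(1→")
    assert unit.backbone_length == 2
    assert min_window(unit, 6) == 5
    frags = enumerate_fragments(unit, 6)
    # a six-residue backbone path Glc-Rha-Glc-Rha-Glc-Rha must be found
    assert any(
        dict(f.composition()) == {"Glc": 3, "Rha": 3} for f in frags
    )
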