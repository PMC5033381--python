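"""Glycan tree model: parsing, canonicalization, composition, chaining."""

import pytest

from glycoelucidate import (
    Composition,
    GlycanTree,
    Linkage,
    MonosaccharideIdentity,
    RepeatUnit,
    isomorphic,
    parse_condensed,
)
from glycoelucidate.tree import GlycanParseError, same_polymer


def test_parse_two_residue_chain():
    t = parse_condensed("α-D-Glcp-(1→2)-α-D-Galp")
    assert isinstance(t, GlycanTree)
    assert len(t) == 2
    root = t.residues[t.root_id]
    assert root.name == "Gal" and root.anomeric_config == "alpha"
    ((child, parent, pos),) = t.edges()
    assert t.residues[child].name == "Glc" and pos == 2


def test_parse_published_repeat_unit(eps_unit):
    assert isinstance(eps_unit, RepeatUnit)
    assert len(eps_unit) == 6
    # exactly one branch point, the 2,4-disubstituted galactose
    branched = [
        rid
        for rid in eps_unit.tree.residues
        if eps_unit.substituted_positions(rid) == frozenset({2, 4})
    ]
    assert len(branched) == 1
    assert eps_unit.tree.residues[branched[0]].name == "Gal"


def test_parse_os211_linear(os211):
    assert isinstance(os211, GlycanTree)
    names_from_root = [os211.residues[os211.root_id].name]
    node = os211.root_id
    while True:
        kids = os211.children(node)
        if not kids:
            break
        node = kids[0][0]
        names_from_root.append(os211.residues[node].name)
    assert names_from_root == ["Gal", "GalA", "6dTal", "Glc"]


@pytest.mark.parametrize(
    "bad",
    [
        "α-D-Glxp-(1→2)-α-D-Galp",          # unknown residue token
        "α-D-Glcp-(1→7)-α-D-Galp",          # impossible position
        "Glcp-(1→2)-[Galp-(1→2)]-Galp",     # duplicate substitution
        "Glcp-(1→2)-",                       # dangling linkage
        "→4)-Glcp-(1→2)-Galp",              # repeat head without exit tail
        "[Glcp]-Galp",                       # branch without linkage
    ],
)
def test_parse_errors(bad):
    with pytest.raises(GlycanParseError):
        parse_condensed(bad)


def test_roundtrip_and_canonical_idempotence(eps_unit, os211):
    for obj in (eps_unit, os211):
        text = obj.canonical_form()
        again = parse_condensed(text)
        assert again.canonical_form() == text


def test_canonical_invariant_under_hand_reordering():
    # same two-branch tree entered with branches swapped
    a = parse_condensed("Glcp-(1→2)-[Rhap-(1→3)]-Galp")
    b = parse_condensed("Rhap-(1→3)-[Glcp-(1→2)]-Galp")
    assert isomorphic(a, b)


def test_single_residue_canonical():
    t = parse_condensed("β-D-Glcp")
    assert t.canonical_form() == "β-D-Glcp"


def test_composition(eps_unit, os211):
    assert dict(eps_unit.composition()) == {"Glc": 2, "Gal": 2, "GalA": 1, "6dTal": 1}
    assert dict(os211.composition("class")) == {"Hex": 2, "HexA": 1, "dHex": 1}
    single = parse_condensed("Rhap")
    assert dict(single.composition()) == {"Rha": 1}


def test_composition_matches_mixed_levels():
    comp = Composition({"Glc": 2, "Gal": 1, "GalA": 1})
    assert comp.matches(Composition({"Hex": 3, "HexA": 1}))
    assert comp.matches(Composition({"Glc": 2, "Hex": 1, "HexA": 1}))
    assert not comp.matches(Composition({"Hex": 4}))
    assert not comp.matches(Composition({"Glc": 3, "HexA": 1}))


@pytest.mark.parametrize("k", [1, 2, 4])
def test_chaining_edge_count(eps_unit, k):
    chain = eps_unit.chain(k)
    assert len(chain) == 6 * k
    assert len(chain.parent) == 6 * k - 1


def test_chain_reducing_end_is_last_copy(eps_unit):
    chain = eps_unit.chain(3)
    assert chain.root_id.endswith("/2")


def test_exit_attachment_must_be_free():
    tree = parse_condensed("Glcp-(1→4)-Galp")
    with pytest.raises(ValueError):
        RepeatUnit(tree=tree, exit_attachment=(tree.root_id, 4))  # already substituted


def test_rotations_same_polymer(eps_unit):
    rots = eps_unit.rotations()
    # 5 backbone residues -> 5 phases
    assert len(rots) == eps_unit.backbone_length == 5
    assert len({r.canonical_form() for r in rots}) == 5
    for r in rots:
        assert same_polymer(r, eps_unit)
        assert dict(r.composition()) == dict(eps_unit.composition())


def test_json_roundtrip(eps_unit):
    again = RepeatUnit.from_json(eps_unit.to_json())
    assert isomorphic(again, eps_unit)


def test_duplicate_position_rejected_by_model():
    with pytest.raises(ValueError):
        GlycanTree(
            residues={
                "a": MonosaccharideIdentity("Glc"),
                "b": MonosaccharideIdentity("Gal"),
                "c": MonosaccharideIdentity("Gal"),
            },
            parent={"b": ("a", Linkage(3)), "c": ("a", Linkage(3))},
            root_id="a",
        )
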