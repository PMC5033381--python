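"""Mass arithmetic: frozen reference values and additivity invariants."""

from collections import Counter

import pytest

from glycoelucidate import (
    DerivatizationScheme,
    Methylation,
    MonosaccharideIdentity,
    Reduction,
    derivative_mz,
    fragment_ion_mzs,
    glycan_mass,
    parse_condensed,
    residue_mass,
    unit_average_mass,
)
from glycoelucidate.masses import (
    CYSTEINE_METHYL_ESTER,
    MONOISOTOPIC,
    WATER,
    formula_mass,
)


@pytest.mark.parametrize(
    "name,expected",
    [("Glc", 162.0528), ("Fuc", 146.0579), ("GalA", 176.0321)],
)
def test_native_anhydro_residue_masses(name, expected):
    assert residue_mass(MonosaccharideIdentity(name)) == pytest.approx(expected, abs=1e-4)


def test_free_hexose_mass():
    t = parse_condensed("Glcp")
    assert glycan_mass(t).neutral_mass == pytest.approx(180.0634, abs=1e-4)


def test_os211_native_mass(os211):
    # 2 Hex + 1 HexA + 1 dHex + H2O
    assert glycan_mass(os211).neutral_mass == pytest.approx(664.2062, abs=1e-4)


def test_os411_sodiated_mz():
    t = parse_condensed(
        "Glcp-(1→4)-Glcp-(1→4)-Glcp-(1→4)-Glcp-(1→4)-GalpA-(1→4)-Rhap"
    )
    ion = glycan_mass(t, DerivatizationScheme(adduct="+Na"))
    assert ion.neutral_mass == pytest.approx(988.3118, abs=1e-3)
    assert ion.mz == pytest.approx(1011.3011, abs=1e-3)


def test_penta_tms_cysteine_derivative_of_hexose():
    """The hexose/L-cysteine-methyl-ester condensate with five TMS groups,
    protonated — the diagnostic GC-MS ion for D/L assignment."""
    scheme = DerivatizationScheme(
        condensation_partner=CYSTEINE_METHYL_ESTER, silylation_count=5, adduct="+H"
    )
    ion = derivative_mz(MonosaccharideIdentity("Glc"), scheme)
    assert ion.mz == pytest.approx(658.2931, abs=0.005)


def test_underivatized_cysteine_condensate():
    scheme = DerivatizationScheme(condensation_partner=CYSTEINE_METHYL_ESTER)
    ion = derivative_mz(MonosaccharideIdentity("Glc"), scheme)
    # C10H19NO7S
    assert ion.neutral_mass == pytest.approx(297.0882, abs=1e-4)


def test_deoxyhexose_cysteine_tms_derivative_matches_formula_oracle():
    scheme = DerivatizationScheme(
        condensation_partner=CYSTEINE_METHYL_ESTER, silylation_count=4, adduct="+H"
    )
    ion = derivative_mz(MonosaccharideIdentity("Fuc"), scheme)
    oracle = Counter({"C": 6, "H": 12, "O": 5})  # free dHex
    oracle += Counter(CYSTEINE_METHYL_ESTER)
    oracle -= WATER
    for _ in range(4):
        oracle += Counter({"C": 3, "H": 8, "Si": 1})
    expected = formula_mass(oracle) + MONOISOTOPIC["H"] - 0.000549
    assert ion.mz == pytest.approx(expected, abs=1e-6)


def test_silylation_count_capped():
    scheme = DerivatizationScheme(
        condensation_partner=CYSTEINE_METHYL_ESTER, silylation_count=12
    )
    with pytest.raises(ValueError):
        derivative_mz(MonosaccharideIdentity("Glc"), scheme)


def test_cd3_vs_ch3_permethylation_delta(eps_unit):
    ch3 = glycan_mass(eps_unit, DerivatizationScheme(methylation=Methylation.CH3))
    cd3 = glycan_mass(eps_unit, DerivatizationScheme(methylation=Methylation.CD3))
    d_count = cd3.formula["D"]
    assert d_count > 0 and d_count % 3 == 0
    assert cd3.neutral_mass - ch3.neutral_mass == pytest.approx(
        3.018831 * (d_count // 3), abs=1e-4
    )


def test_reduction_deltas(os211):
    native = glycan_mass(os211).neutral_mass
    bh4 = glycan_mass(os211, DerivatizationScheme(reduction=Reduction.BH4)).neutral_mass
    bd4 = glycan_mass(os211, DerivatizationScheme(reduction=Reduction.BD4)).neutral_mass
    assert bh4 - native == pytest.approx(2.015650, abs=1e-5)
    assert bd4 - bh4 == pytest.approx(1.006277, abs=1e-5)


def test_fragment_ions_disaccharide():
    di = parse_condensed("Glcp-(1→4)-Glcp")
    ions = {i.label: i for i in fragment_ion_mzs(di)}
    assert ions["y1"].neutral_mass == pytest.approx(180.0634, abs=1e-4)
    assert ions["b1"].neutral_mass == pytest.approx(162.0528, abs=1e-4)
    # documented 1,5X convention: y + CO
    assert ions["x15_1"].neutral_mass - ions["y1"].neutral_mass == pytest.approx(
        27.994915, abs=1e-5
    )


def test_fragment_ions_single_residue_empty():
    assert fragment_ion_mzs(parse_condensed("Glcp")) == []


@pytest.mark.parametrize(
    "scheme",
    [
        DerivatizationScheme(),
        DerivatizationScheme(methylation=Methylation.CD3),
        DerivatizationScheme(reduction=Reduction.BD4),
    ],
)
def test_b_plus_y_equals_parent(eps_unit, scheme):
    tree = eps_unit.tree
    full = glycan_mass(tree, scheme).neutral_mass
    ions = fragment_ion_mzs(tree, scheme)
    by_edge = {}
    for ion in ions:
        by_edge.setdefault(ion.cleaved_edge, {})[ion.ion_type] = ion.neutral_mass
    assert by_edge
    for masses in by_edge.values():
        assert masses["b"] + masses["y"] == pytest.approx(full, abs=1e-6)


def test_mutually_exclusive_scheme_flags():
    with pytest.raises(ValueError):
        DerivatizationScheme(methylation=Methylation.CH3, silylation_count=2)
    with pytest.raises(ValueError):
        DerivatizationScheme(
            reduction=Reduction.BH4, condensation_partner=CYSTEINE_METHYL_ESTER
        )


def test_unit_average_mass(eps_unit):
    # 4 Hex + 1 HexA + 1 dHex anhydro, average masses, no terminal water
    assert unit_average_mass(eps_unit) == pytest.approx(970.83, abs=0.05)
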