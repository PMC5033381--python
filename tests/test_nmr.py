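"""NMR-side utilities: signal counting, HMBC edges, consistency checks."""

import pandas as pd
import pytest

from glycoelucidate import (
    HMBCCorrelation,
    NMRTable,
    check_structure_vs_hmbc,
    count_anomeric_signals,
    hmbc_to_edges,
)
from glycoelucidate import datasets
from glycoelucidate.nmr import LabelledEdge, anomeric_signal_multiplicities


@pytest.fixture(scope="module")
def table():
    return datasets.eps35624_nmr_table()


def test_four_anomeric_carbons_in_100_104(table):
    assert count_anomeric_signals(table, "C", (100.0, 104.0)) == 4


def test_six_anomeric_protons(table):
    assert count_anomeric_signals(table, "H", (4.3, 5.7)) == 6


def test_degenerate_window(table):
    assert count_anomeric_signals(table, "C", (0.0, 0.0)) == 0


def test_coinciding_signals_counted_once_with_multiplicity(table):
    """The two anomeric carbons at 97.47 ppm overlap into one signal of
    double intensity."""
    mult = anomeric_signal_multiplicities(table, "C", (97.0, 104.0))
    assert mult[97.47] == 2
    assert count_anomeric_signals(table, "C", (97.0, 104.0)) == 5


def test_empty_table_rejected():
    frame = pd.DataFrame(
        columns=["residue", "identity", "nucleus"] + [f"P{i}" for i in range(1, 7)]
    )
    with pytest.raises(ValueError):
        count_anomeric_signals(NMRTable(frame), "C", (0, 200))


def test_hmbc_to_edges_published_set():
    edges = hmbc_to_edges(datasets.eps35624_hmbc_correlations())
    assert set((e.donor, e.position, e.acceptor) for e in edges) == {
        ("A", 4, "B"),
        ("B", 4, "C"),
        ("D", 4, "E"),   # H-4(E) -> C-1(D): carbon-side anomeric, normalized
        ("F", 2, "E"),
    }


def test_hmbc_to_edges_empty_and_idempotent():
    assert hmbc_to_edges([]) == []
    corr = datasets.eps35624_hmbc_correlations()
    assert hmbc_to_edges(corr + corr) == hmbc_to_edges(corr)


def test_hmbc_without_anomeric_terminus_warns():
    with pytest.warns(UserWarning):
        edges = hmbc_to_edges([HMBCCorrelation("A", 3, "B", 4)])
    assert edges == []


def test_structure_vs_hmbc_consistent(eps_unit):
    report = check_structure_vs_hmbc(
        eps_unit, datasets.eps35624_hmbc_correlations(), datasets.eps35624_labels()
    )
    assert report.consistent
    assert len(report.confirmed) == 4
    # bonds the correlations never covered: C-(1→4)-D and the exit E-(1→4)-A
    assert set((e.donor, e.position, e.acceptor) for e in report.uncovered) == {
        ("C", 4, "D"),
        ("E", 4, "A"),
    }


def test_structure_vs_hmbc_contradiction(eps_unit):
    fabricated = datasets.eps35624_hmbc_correlations() + [
        HMBCCorrelation("F", 1, "E", 3)
    ]
    report = check_structure_vs_hmbc(eps_unit, fabricated, datasets.eps35624_labels())
    assert not report.consistent
    assert LabelledEdge("F", 3, "E") in report.contradicting


def test_structure_vs_empty_correlations(eps_unit):
    report = check_structure_vs_hmbc(eps_unit, [], datasets.eps35624_labels())
    assert report.consistent
    assert len(report.uncovered) == 6  # 5 intra-unit bonds + the exit


def test_full_simulated_correlations_cover_everything(eps_unit):
    corr = [
        HMBCCorrelation(label_c, 1, label_p, pos)
        for label_c, label_p, pos in [
            ("A", "B", 4), ("B", "C", 4), ("C", "D", 4),
            ("D", "E", 4), ("F", "E", 2), ("E", "A", 4),
        ]
    ]
    report = check_structure_vs_hmbc(eps_unit, corr, datasets.eps35624_labels())
    assert report.consistent and not report.uncovered
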