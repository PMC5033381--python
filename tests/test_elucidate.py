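"""The constraint solver: PMAA simulation, candidate spaces, pruning."""

import pytest

from glycoelucidate import (
    AdjacencyConstraint,
    Composition,
    FragmentObservation,
    LinkageEdge,
    ObservationSet,
    PMAAPattern,
    StructureElucidator,
    candidate_space,
    elucidate,
    parse_condensed,
    prune,
    simulate_pmaa,
)
from glycoelucidate.tree import same_polymer


def _pat_set(patterns):
    return sorted((p.sugar, tuple(sorted(p.positions)), p.detectable) for p in patterns)


def test_simulate_pmaa_os211(os211):
    pats = _pat_set(simulate_pmaa(os211))
    assert pats == [
        ("6dTal", (4,), True),
        ("Gal", (4,), True),
        ("GalA", (4,), False),   # uronic acids escape the method
        ("Glc", (), True),
    ]


def test_simulate_pmaa_repeat_unit(eps_unit):
    pats = _pat_set(simulate_pmaa(eps_unit))
    assert pats == [
        ("6dTal", (4,), True),
        ("Gal", (2, 4), True),
        ("Gal", (4,), True),
        ("GalA", (4,), False),
        ("Glc", (), True),
        ("Glc", (4,), True),     # the exit bond counts on the attachment residue
    ]


def test_simulate_pmaa_single_residue():
    pats = simulate_pmaa(parse_condensed("Galp"))
    assert len(pats) == 1 and pats[0].positions == frozenset()


def test_two_residue_candidate_count():
    """{Glc, Gal} with terminal Glc and an n-substituted Gal: one candidate
    tree per allowed substitution position."""
    pmaa = [
        PMAAPattern("Glc", frozenset()),
        PMAAPattern("Gal", frozenset({3})),
    ]
    cands = candidate_space(
        Composition({"Glc": 1, "Gal": 1}), pmaa, mode="fragment"
    )
    assert len(cands) == 1
    for n in (2, 4, 6):
        more = candidate_space(
            Composition({"Glc": 1, "Gal": 1}),
            [PMAAPattern("Glc", frozenset()), PMAAPattern("Gal", frozenset({n}))],
            mode="fragment",
        )
        assert len(more) == 1
        assert more[0].canonical_form("name") == f"Glcp-(1→{n})-Galp"


def test_os211_deduction(os211):
    """Composition + PMAA + reducing-end class leave two sequences; the
    aldobiuronic HexA-Hex adjacency forces Glc-6dTal-GalA-Gal."""
    pmaa = simulate_pmaa(os211)
    cands = candidate_space(os211.composition(), pmaa, mode="fragment", reducing_class="Hex")
    assert len(cands) == 2
    obs = ObservationSet(
        composition=os211.composition(),
        pmaa=pmaa,
        adjacencies=[AdjacencyConstraint(donor="HexA", acceptor="Hex")],
    )
    kept = prune(cands, obs)
    assert len(kept) == 1
    assert kept[0].canonical_form("name") == "Glcp-(1→4)-6dTalp-(1→4)-GalpA-(1→4)-Galp"


def test_candidate_space_cap():
    with pytest.raises(ValueError, match="cap"):
        candidate_space(Composition({"Glc": 9}), [], max_residues=8)


def test_prune_empty_observation_is_vacuous(eps_unit, eps_observations):
    cands = candidate_space(eps_observations.composition, eps_observations.pmaa)
    empty = ObservationSet(composition=eps_observations.composition)
    assert prune(list(cands), empty) == list(cands)


def test_prune_adjacency_eliminates(eps_observations):
    cands = candidate_space(eps_observations.composition, eps_observations.pmaa)
    # candidates lacking any HexA->Hex bond must all be dropped
    obs = ObservationSet(
        composition=eps_observations.composition,
        adjacencies=[AdjacencyConstraint(donor="HexA", acceptor="dHex")],
    )
    kept = prune(cands, obs)
    for c in kept:
        assert any(
            c.tree.residues[child].name == "GalA"
            and c.tree.residues[parent].name == "6dTal"
            for child, parent, _ in c.edges()
        )


def test_full_elucidation_is_unique_and_correct(eps_unit, eps_observations):
    res = StructureElucidator(eps_observations).fit()
    assert res.is_unique
    assert same_polymer(res.structure, eps_unit.strip_attrs())
    # report counts are monotone non-increasing through the prune stages
    prune_counts = [after for label, _, after in res.report.stages[1:]]
    assert prune_counts == sorted(prune_counts, reverse=True)


def test_removing_observations_grows_result(eps_observations):
    full = elucidate(eps_observations)
    no_frags = ObservationSet(
        composition=eps_observations.composition,
        pmaa=eps_observations.pmaa,
        adjacencies=eps_observations.adjacencies,
        hmbc=eps_observations.hmbc,
    )
    relaxed = elucidate(no_frags)
    full_keys = {c.polymer_canonical_form() for c in full.candidates}
    relaxed_keys = {c.polymer_canonical_form() for c in relaxed.candidates}
    assert full_keys <= relaxed_keys


def test_inconsistent_observations_reported(eps_observations):
    bad = ObservationSet(
        composition=eps_observations.composition,
        pmaa=eps_observations.pmaa,
        fragments=[
            # four consecutive deoxyhexoses cannot occur when the unit
            # carries a single 6dTal, whatever the topology
            FragmentObservation(
                name="impossible",
                composition=Composition({"dHex": 4}),
                reducing_end="dHex",
            )
        ],
    )
    res = elucidate(bad)
    assert res.is_inconsistent
    assert res.report.first_unsatisfiable == "fragment:impossible"


def test_hmbc_substitution_refinement_disambiguates(eps_observations):
    """Name-level HMBC alone admits the GalA-(Glc-)Gal-Gal backbone; the
    assigned substitution patterns pin the branch next to the reducing-side
    galactose."""
    stripped = ObservationSet(
        composition=eps_observations.composition,
        pmaa=eps_observations.pmaa,
        fragments=eps_observations.fragments,
        adjacencies=eps_observations.adjacencies,
        hmbc=[
            LinkageEdge(e.donor, e.position, e.acceptor) for e in eps_observations.hmbc
        ],
    )
    res_stripped = elucidate(stripped)
    res_full = elucidate(eps_observations)
    assert res_full.is_unique
    assert res_stripped.n_candidates > res_full.n_candidates


def test_summary_mentions_result(eps_observations):
    res = elucidate(eps_observations)
    text = res.summary()
    assert "unique structure" in text
    assert "candidate space" in text


def test_edge_screening_matches_unscreened_result(eps_observations):
    """Applying the linkage evidence during generation is a pure
    performance device: the survivors are identical."""
    fast = StructureElucidator(eps_observations, screen_with_edges=True).fit()
    slow = StructureElucidator(eps_observations, screen_with_edges=False).fit()
    assert [c.polymer_canonical_form() for c in fast.candidates] == [
        c.polymer_canonical_form() for c in slow.candidates
    ]


def test_elimination_plot_smoke(eps_observations):
    import matplotlib

    matplotlib.use("Agg")
    res = elucidate(eps_observations)
    ax = res.plot_elimination()
    assert ax.patches  # one bar per stage
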