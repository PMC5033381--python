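"""Synthetic world: determinism, validity, observation projection."""

import pytest

from glycoelucidate import (
    GeneratorParams,
    SugarClass,
    elucidate,
    random_repeat_unit,
    simulate_observations,
    simulate_pmaa,
)
from glycoelucidate import datasets
from glycoelucidate.tree import same_polymer


def test_seed_determinism():
    a = random_repeat_unit(GeneratorParams(seed=1))
    b = random_repeat_unit(GeneratorParams(seed=1))
    assert a.canonical_form() == b.canonical_form()
    assert (
        random_repeat_unit(GeneratorParams(seed=2)).canonical_form()
        != a.canonical_form()
    )


def test_branch_probability_zero_gives_linear_chain():
    unit = random_repeat_unit(GeneratorParams(seed=5, branch_probability=0.0))
    assert all(len(unit.tree.children(r)) <= 1 for r in unit.tree.residues)


@pytest.mark.parametrize("seed", range(0, 200, 7))
def test_generated_units_are_valid(seed):
    unit = random_repeat_unit(GeneratorParams(seed=seed))
    unit.tree.validate()
    lo, hi = GeneratorParams().size_range
    assert lo <= len(unit) <= hi
    # solver-compatible world: at most two glycosylated positions anywhere
    for rid in unit.tree.residues:
        assert len(unit.substituted_positions(rid)) <= 2


def test_bad_params_rejected():
    with pytest.raises(ValueError):
        GeneratorParams(alphabet=())
    with pytest.raises(ValueError):
        GeneratorParams(branch_probability=1.5)
    with pytest.raises(ValueError):
        GeneratorParams(size_range=(1, 1))


def test_observation_projection_of_published_unit(eps_unit):
    params = GeneratorParams(seed=0, fragment_dropout=0.0, hmbc_coverage=1.0)
    obs = simulate_observations(eps_unit, params)
    assert dict(obs.composition) == {"Glc": 2, "Gal": 2, "GalA": 1, "6dTal": 1}
    # uronic patterns are masked; five detectable species remain
    pats = sorted((p.sugar, tuple(sorted(p.positions))) for p in obs.pmaa)
    assert pats == [
        ("6dTal", (4,)),
        ("Gal", (2, 4)),
        ("Gal", (4,)),
        ("Glc", ()),
        ("Glc", (4,)),
    ]
    assert all(p.detectable for p in obs.pmaa)
    assert obs.adjacencies and obs.adjacencies[0].donor == "GalA"
    assert len(obs.hmbc) == 6  # full coverage: 5 intra bonds + exit


def test_undetectable_pmaa_opt_in(eps_unit):
    params = GeneratorParams(seed=0)
    obs = simulate_observations(eps_unit, params, include_undetectable_pmaa=True)
    assert any(not p.detectable and p.sugar == "GalA" for p in obs.pmaa)


def test_full_dropout_removes_fragments(eps_unit):
    obs = simulate_observations(eps_unit, GeneratorParams(seed=0, fragment_dropout=1.0))
    assert obs.fragments == []


def test_dropout_monotone_on_matched_seed(eps_unit):
    names = []
    for dropout in (0.0, 0.4, 0.8):
        obs = simulate_observations(
            eps_unit, GeneratorParams(seed=9, fragment_dropout=dropout)
        )
        names.append({f.name for f in obs.fragments})
    assert names[2] <= names[1] <= names[0]


def test_recovery_with_full_information():
    """With no dropout and full HMBC coverage the true polymer is always
    recovered, uniquely for most units of up to six residues."""
    unique = 0
    n = 15
    for seed in range(n):
        params = GeneratorParams(
            seed=seed, size_range=(3, 6), fragment_dropout=0.0, hmbc_coverage=1.0
        )
        unit = random_repeat_unit(params)
        res = elucidate(simulate_observations(unit, params))
        assert any(same_polymer(c, unit.strip_attrs()) for c in res.candidates)
        unique += res.is_unique
    assert unique >= 0.9 * n
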