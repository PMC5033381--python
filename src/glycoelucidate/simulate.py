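"""Random repeat-unit structures and simulated observation sets.

The generator emulates the evidence channels of a wet-lab structure
determination — composition counts, PMAA linkage multisets, hydrolysis
fragment observations, aldobiuronic-type adjacencies and HMBC-derived
bonds — for arbitrary generated repeat units, so every pipeline stage is
testable without measured data.  Noise is modelled as *omission*
(fragment dropout, incomplete HMBC coverage), never corruption: the real
evidence channels are qualitative presence calls.

One integer seed drives all stochastic choices through per-channel
`numpy` generator streams, so identical parameters reproduce identical
fixtures and increasing dropout monotonically removes observations on
matched seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elucidate import (
    AdjacencyConstraint,
    FragmentObservation,
    LinkageEdge,
    ObservationSet,
    PMAAPattern,
    simulate_pmaa,
)
from .fragments import enumerate_fragments
from .residues import MonosaccharideIdentity, SugarClass, sugar_class_of
from .tree import GlycanTree, Linkage, RepeatUnit

#: Default residue alphabet with sampling weights: common neutral hexoses
#: dominate, with occasional 6-deoxy sugars and hexuronic acids, the mix
#: typical of acidic bacterial heteropolysaccharide repeat units.
DEFAULT_ALPHABET: tuple[tuple[str, float], ...] = (
    ("Glc", 3.0),
    ("Gal", 3.0),
    ("Man", 1.5),
    ("Rha", 1.0),
    ("Fuc", 0.5),
    ("6dTal", 0.5),
    ("GlcA", 0.5),
    ("GalA", 0.5),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic world (see module docstring for defaults)."""

    size_range: tuple[int, int] = (3, 8)
    alphabet: tuple[tuple[str, float], ...] = DEFAULT_ALPHABET
    branch_probability: float = 0.2
    allowed_positions: tuple[int, ...] = (2, 3, 4, 6)
    fragment_dropout: float = 0.3
    hmbc_coverage: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (2 <= lo <= hi):
            raise ValueError("size range must satisfy 2 <= lo <= hi")
        if not self.alphabet:
            raise ValueError("empty residue alphabet")
        for name, w in self.alphabet:
            sugar_class_of(name)
            if w < 0:
                raise ValueError("negative sampling weight")
        for p in (self.branch_probability, self.fragment_dropout, self.hmbc_coverage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _rng(params: GeneratorParams, channel: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, channel])


def random_repeat_unit(params: GeneratorParams) -> RepeatUnit:
    """Sample a valid repeat unit.

    Residues are drawn from the weighted alphabet; the tree grows from
    the exit-donor root, each new residue attaching to a uniformly chosen
    residue that still has a free allowed position (second substituents
    admitted with ``branch_probability``, at most two substituents per
    residue).  The exit attachment goes to a residue with at most one
    intra-unit substituent so no residue exceeds two glycosylated
    positions — keeping the generated world inside the solver's default
    search space.
    """
    rng = _rng(params, 0)
    lo, hi = params.size_range
    n = int(rng.integers(lo, hi + 1))
    names = [name for name, _ in params.alphabet]
    weights = np.array([w for _, w in params.alphabet], dtype=float)
    weights /= weights.sum()
    idents = [
        MonosaccharideIdentity(str(rng.choice(names, p=weights))) for _ in range(n)
    ]
    residues = {f"r{i}": idents[i] for i in range(n)}
    parent: dict[str, tuple[str, Linkage]] = {}
    n_children = {f"r{i}": 0 for i in range(n)}
    for i in range(1, n):
        rid = f"r{i}"
        while True:
            hosts = [
                h
                for h in list(residues)[:i]
                if n_children[h] < 2
                and _free_positions(residues[h], parent, h, params.allowed_positions)
            ]
            host = str(rng.choice(hosts))
            if n_children[host] == 1 and rng.random() >= params.branch_probability:
                # prefer chain growth; re-draw rather than force a branch
                unbranched = [h for h in hosts if n_children[h] == 0]
                if unbranched:
                    host = str(rng.choice(unbranched))
            free = _free_positions(residues[host], parent, host, params.allowed_positions)
            if free:
                pos = int(rng.choice(sorted(free)))
                parent[rid] = (host, Linkage(pos))
                n_children[host] += 1
                break
    tree = GlycanTree(residues=residues, parent=parent, root_id="r0")
    att_candidates = [
        rid
        for rid in sorted(residues)
        if n_children[rid] <= 1
        and _free_positions(residues[rid], parent, rid, params.allowed_positions)
    ]
    att = str(rng.choice(att_candidates))
    att_pos = int(
        rng.choice(sorted(_free_positions(residues[att], parent, att, params.allowed_positions)))
    )
    return RepeatUnit(tree=tree, exit_attachment=(att, att_pos))


def _free_positions(
    ident: MonosaccharideIdentity,
    parent: dict[str, tuple[str, Linkage]],
    rid: str,
    allowed: tuple[int, ...],
) -> set[int]:
    used = {l.parent_position for (p, l) in parent.values() if p == rid}
    return (set(allowed) & set(ident.hydroxyl_positions)) - used


def simulate_observations(
    unit: RepeatUnit,
    params: GeneratorParams,
    include_undetectable_pmaa: bool = False,
) -> ObservationSet:
    """Project a repeat unit onto the observation channels.

    * composition: exact name-level counts;
    * PMAA: simulated patterns, uronic residues masked (dropped) unless
      ``include_undetectable_pmaa`` keeps them flagged;
    * fragments: every distinct (composition, reducing end) signature of
      fragments of 3..n residues, each surviving dropout independently;
    * adjacencies: one constraint per hexuronic-donor bond (the
      acid-stable aldobiuronic signature);
    * HMBC: each polymer bond observed with probability ``hmbc_coverage``.
    """
    patterns = []
    for pat in simulate_pmaa(unit):
        if pat.detectable:
            patterns.append(pat)
        elif include_undetectable_pmaa:
            patterns.append(pat)
    n = len(unit)
    signatures: dict[tuple, FragmentObservation] = {}
    for size in range(3, n + 1):
        for frag in enumerate_fragments(unit, size):
            comp = frag.composition()
            key = (tuple(sorted(comp.items())), frag.reducing_end)
            if key not in signatures:
                signatures[key] = FragmentObservation(
                    name=f"frag{size}_{len(signatures)}",
                    composition=comp,
                    reducing_end=frag.reducing_end,
                )
    rng = _rng(params, 1)
    fragments = [
        obs
        for key, obs in sorted(signatures.items())
        if rng.random() >= params.fragment_dropout
    ]
    tree = unit.tree
    adjacencies = []
    for child, parent_id, _ in unit.edges():
        if tree.residues[child].sugar_class == SugarClass.HEXA:
            adjacencies.append(
                AdjacencyConstraint(
                    donor=tree.residues[child].name, acceptor=tree.residues[parent_id].name
                )
            )
    adjacencies = sorted(set(adjacencies), key=lambda a: (a.donor, a.acceptor))
    rng = _rng(params, 2)
    hmbc = []
    for child, parent_id, pos in sorted(unit.edges()):
        if rng.random() < params.hmbc_coverage:
            # the assignment work behind an HMBC table also establishes
            # each residue's glycosylation pattern, so simulated edges
            # carry the substitution refinements
            hmbc.append(
                LinkageEdge(
                    donor=tree.residues[child].name,
                    position=pos,
                    acceptor=tree.residues[parent_id].name,
                    donor_substitutions=unit.substituted_positions(child),
                    acceptor_substitutions=unit.substituted_positions(parent_id),
                )
            )
    seen: set[tuple] = set()
    hmbc_unique = []
    for e in hmbc:
        k = (e.donor, e.position, e.acceptor)
        if k not in seen:
            seen.add(k)
            hmbc_unique.append(e)
    return ObservationSet(
        composition=unit.composition(),
        pmaa=patterns,
        fragments=fragments,
        adjacencies=adjacencies,
        hmbc=hmbc_unique,
    )
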