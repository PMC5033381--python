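"""Constraint-based elucidation of repeat-unit topology.

The solver reproduces the classical deduction chain for a bacterial
exopolysaccharide repeat unit:

1. *Candidate generation*: every repeat-unit (or fragment) topology over
   the observed monosaccharide composition whose simulated permethylation
   (PMAA) linkage pattern is compatible with the observed pattern
   multiset.  PMAA observes, per residue, which ring positions were
   glycosylated; uronic acids are invisible to the method, so their
   patterns may be absent from the observations.
2. *Pruning*: candidates must be able to produce every observed
   hydrolysis fragment (composition + reducing-end class, optionally a
   b-ion sequence from the non-reducing terminus), must contain every
   required adjacency (e.g. the HexA→Hex bond implied by a surviving
   aldobiuronic acid), and must contain every glycosidic bond read from
   inter-residue HMBC correlations.

The search is pure constraint satisfaction — candidates are never scored
or ranked, matching the qualitative nature of the evidence.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from collections import Counter
from dataclasses import dataclass, field

from . import __version__
from .fragments import enumerate_fragments, has_linear_nonreducing_prefix
from .residues import (
    MonosaccharideIdentity,
    SugarClass,
    identities_match,
    is_class_token,
    sugar_class_of,
)
from .tree import Composition, GlycanTree, Linkage, RepeatUnit

_LINK = {p: Linkage(p) for p in (2, 3, 4, 5, 6)}

DEFAULT_ALLOWED_POSITIONS = (2, 3, 4, 6)
DEFAULT_MAX_RESIDUES = 8
DEFAULT_MAX_SUBSTITUTIONS = 2


# ---------------------------------------------------------------------------
# observation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PMAAPattern:
    """One species from a permethylation linkage analysis: a sugar (name or
    class token) glycosylated at ``positions`` (empty = terminal residue).
    ``detectable`` is False for uronic acids, which escape the method."""

    sugar: str
    positions: frozenset[int]
    detectable: bool = True
    abundance: float | None = None  # stored, never used quantitatively

    def __post_init__(self) -> None:
        sugar_class_of(self.sugar)
        bad = set(self.positions) - {2, 3, 4, 6}
        if bad:
            raise ValueError(
                f"pyranose PMAA positions must lie in {{2,3,4,6}}, got {sorted(bad)}"
            )

    def key(self) -> tuple[str, frozenset[int]]:
        return (self.sugar, self.positions)


@dataclass(frozen=True)
class FragmentObservation:
    """A hydrolysis fragment seen by MS.

    ``composition`` and ``reducing_end`` (name or class tokens) identify
    the fragment; ``b_prefix`` is an optional residue sequence read from
    the non-reducing terminus via b ions, and ``y_compositions`` are the
    compositions of reducing-side single-cleavage (y) pieces seen in the
    same MS/MS spectrum.  All of them must be explicable by *one*
    fragment structure — the y series is what places a branch relative
    to the reducing end."""

    name: str
    composition: Composition
    reducing_end: str
    b_prefix: tuple[str, ...] = ()
    y_compositions: tuple[Composition, ...] = ()

    def __post_init__(self) -> None:
        if self.composition.total < 2:
            raise ValueError("a fragment observation needs at least 2 residues")
        sugar_class_of(self.reducing_end)
        for s in self.b_prefix:
            sugar_class_of(s)
        for comp in self.y_compositions:
            if comp.total >= self.composition.total:
                raise ValueError("a y piece must be smaller than its fragment")


@dataclass(frozen=True)
class AdjacencyConstraint:
    """donor-(1→x)-acceptor must occur somewhere in the structure (the
    position is unconstrained)."""

    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        sugar_class_of(self.donor)
        sugar_class_of(self.acceptor)


@dataclass(frozen=True)
class LinkageEdge:
    """An identity-level glycosidic bond donor-(1→position)-acceptor, as
    reconstructed from an inter-residue HMBC correlation.

    When an NMR assignment has also established the glycosylation
    pattern of the residues involved (via glycosylation shifts), the
    optional ``donor_substitutions`` / ``acceptor_substitutions`` pin
    the bond to residues carrying exactly those substituted positions —
    this is what tells two same-name residues with different linkage
    patterns apart."""

    donor: str
    position: int
    acceptor: str
    donor_substitutions: frozenset[int] | None = None
    acceptor_substitutions: frozenset[int] | None = None

    def __post_init__(self) -> None:
        sugar_class_of(self.donor)
        sugar_class_of(self.acceptor)
        if self.position not in (2, 3, 4, 5, 6):
            raise ValueError("linkage position must be in 2..6")


@dataclass
class ObservationSet:
    """The full evidence set driving an elucidation run."""

    composition: Composition
    pmaa: list[PMAAPattern] = field(default_factory=list)
    fragments: list[FragmentObservation] = field(default_factory=list)
    adjacencies: list[AdjacencyConstraint] = field(default_factory=list)
    hmbc: list[LinkageEdge] = field(default_factory=list)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "composition": dict(sorted(self.composition.items())),
                "pmaa": sorted(
                    (p.sugar, sorted(p.positions), p.detectable) for p in self.pmaa
                ),
                "fragments": sorted(
                    (
                        f.name,
                        sorted(f.composition.items()),
                        f.reducing_end,
                        list(f.b_prefix),
                    )
                    for f in self.fragments
                ),
                "adjacencies": sorted((a.donor, a.acceptor) for a in self.adjacencies),
                "hmbc": sorted((e.donor, e.position, e.acceptor) for e in self.hmbc),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class InconsistentObservations(ValueError):
    """No structure satisfies the observations; names the first constraint
    that eliminated every remaining candidate."""

    def __init__(self, first_unsatisfiable: str):
        self.first_unsatisfiable = first_unsatisfiable
        super().__init__(f"inconsistent observations: {first_unsatisfiable}")


# ---------------------------------------------------------------------------
# PMAA simulation
# ---------------------------------------------------------------------------

def simulate_pmaa(structure: RepeatUnit | GlycanTree) -> list[PMAAPattern]:
    """Predicted PMAA pattern multiset of a structure: one pattern per
    residue with its glycosylated positions (for a repeat unit the exit
    bond counts as a substitution on the attachment residue); uronic
    residues are flagged undetectable."""
    if isinstance(structure, RepeatUnit):
        tree = structure.tree
        sub = structure.substituted_positions
    else:
        tree = structure
        sub = tree.substituted_positions
    patterns = []
    for rid, ident in sorted(tree.residues.items()):
        patterns.append(
            PMAAPattern(
                sugar=ident.name,
                positions=frozenset(sub(rid)),
                detectable=ident.sugar_class != SugarClass.HEXA,
            )
        )
    return patterns


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------

def _expand_composition(composition: Composition) -> list[str]:
    names: list[str] = []
    for name, n in sorted(composition.items()):
        names.extend([name] * n)
    return names


def _pattern_assignments(names: list[str], pmaa: list[PMAAPattern]):
    """Yield one pattern-multiset assignment per distinct typing of the
    residues: a list of (name, positions or None) per residue, where None
    marks an (undetected) uronic residue whose positions are free.

    Every observed pattern must be consumed exactly once; residues left
    without a pattern must be uronic acids.
    """
    patterns = list(pmaa)

    def recurse(i: int, remaining: list[str], acc: list[tuple[str, frozenset[int] | None]]):
        if i == len(patterns):
            for name in remaining:
                if sugar_class_of(name) != SugarClass.HEXA:
                    return
            yield acc + [(name, None) for name in remaining]
            return
        pat = patterns[i]
        tried: set[str] = set()
        for j, name in enumerate(remaining):
            if name in tried or not identities_match(pat.sugar, name):
                continue
            tried.add(name)
            # refine generic residues/classes to the more specific token
            resolved = pat.sugar if is_class_token(name) and not is_class_token(pat.sugar) else name
            yield from recurse(
                i + 1,
                remaining[:j] + remaining[j + 1:],
                acc + [(resolved, pat.positions)],
            )

    seen: set[tuple] = set()
    for assignment in recurse(0, names, []):
        key = tuple(sorted((n, tuple(sorted(p)) if p is not None else None) for n, p in assignment))
        if key not in seen:
            seen.add(key)
            yield assignment


def _position_choices(allowed: tuple[int, ...], max_sub: int):
    for k in range(0, max_sub + 1):
        yield from (frozenset(c) for c in itertools.combinations(allowed, k))


def _enumerate_trees(
    typed: list[tuple[str, frozenset[int]]],
    mode: str,
    reducing_class: SugarClass | None,
):
    """Yield (tree, exit) structures over residues with fixed substitution
    positions.  ``typed[i]`` is (name, substituted positions).  In repeat
    mode one position is consumed by the exit bond and every residue
    donates; in fragment mode the root keeps a free anomeric centre.
    """
    n = len(typed)
    ids = [f"r{i}" for i in range(n)]
    idents = {ids[i]: MonosaccharideIdentity(typed[i][0]) for i in range(n)}
    slots = [(ids[i], p) for i in range(n) for p in sorted(typed[i][1])]
    need = n if mode == "repeat" else n - 1
    if len(slots) != need:
        return

    def type_key(i: int) -> tuple:
        return (typed[i][0], tuple(sorted(typed[i][1])))

    def assign(slot_idx: int, parent_of: dict[str, tuple[str, int]], remaining: list[int], skip_slot: int):
        if slot_idx == len(slots):
            yield dict(parent_of)
            return
        if slot_idx == skip_slot:
            yield from assign(slot_idx + 1, parent_of, remaining, skip_slot)
            return
        acceptor, pos = slots[slot_idx]
        tried: set[tuple] = set()
        for k, di in enumerate(remaining):
            key = type_key(di)
            if key in tried:
                continue
            tried.add(key)
            donor = ids[di]
            if donor == acceptor:
                continue
            parent_of[donor] = (acceptor, pos)
            yield from assign(slot_idx + 1, parent_of, remaining[:k] + remaining[k + 1:], skip_slot)
            del parent_of[donor]

    root_tried: set[tuple] = set()
    for ri in range(n):
        rk = type_key(ri)
        if rk in root_tried:
            continue  # identical residues are interchangeable as roots
        root_tried.add(rk)
        root = ids[ri]
        if reducing_class is not None and idents[root].sugar_class != reducing_class:
            continue
        if n > 1 and not typed[ri][1]:
            continue  # an unsubstituted root cannot hold a multi-residue tree
        donors = [i for i in range(n) if i != ri]
        if mode == "repeat":
            # equivalent exit slots (same residue type, same position) are
            # interchangeable; try one representative of each
            skip_choices, skip_seen = [], set()
            for s, (rid_s, pos_s) in enumerate(slots):
                k = (type_key(int(rid_s[1:])), pos_s, rid_s == root)
                if k not in skip_seen:
                    skip_seen.add(k)
                    skip_choices.append(s)
        else:
            skip_choices = [-1]
        for skip in skip_choices:
            for parent_of in assign(0, {}, donors, skip if mode == "repeat" else -1):
                # validity: parent relation must form a tree rooted at root
                ok = True
                for node in ids:
                    seen = set()
                    cur = node
                    while cur != root:
                        if cur in seen or cur not in parent_of:
                            ok = False
                            break
                        seen.add(cur)
                        cur = parent_of[cur][0]
                    if not ok:
                        break
                if not ok:
                    continue
                tree = GlycanTree._trusted(
                    residues=idents,
                    parent={c: (p, _LINK[pos]) for c, (p, pos) in parent_of.items()},
                    root_id=root,
                )
                if mode == "repeat":
                    yield RepeatUnit._trusted(tree, slots[skip])
                else:
                    yield tree


def _typed_can_host_edges(
    typed: list[tuple[str, frozenset[int]]],
    edges: list[LinkageEdge],
    adjacencies: list[AdjacencyConstraint],
) -> bool:
    """Cheap necessary condition: a typed residue multiset (names + fixed
    substitution sets) can only host a required bond if compatible donor
    and acceptor residues exist.  Used to skip hopeless position choices
    for PMAA-invisible uronic residues before tree enumeration."""
    for e in edges:
        ok = False
        for i, (a_name, a_pos) in enumerate(typed):
            if e.position not in a_pos:
                continue
            if not identities_match(e.acceptor, a_name):
                continue
            if e.acceptor_substitutions is not None and a_pos != e.acceptor_substitutions:
                continue
            # the donor may be the same residue: the exit bond of a
            # short-backbone polymer wraps a residue onto its own type
            for d_name, d_pos in typed:
                if not identities_match(e.donor, d_name):
                    continue
                if e.donor_substitutions is not None and d_pos != e.donor_substitutions:
                    continue
                ok = True
                break
            if ok:
                break
        if not ok:
            return False
    for adj in adjacencies:
        if not any(
            identities_match(adj.donor, typed[j][0])
            and identities_match(adj.acceptor, typed[i][0])
            and typed[i][1]
            for i in range(len(typed))
            for j in range(len(typed))
        ):
            return False
    return True


def candidate_space(
    composition: Composition | dict,
    pmaa: list[PMAAPattern],
    mode: str = "repeat",
    reducing_class: SugarClass | str | None = None,
    max_residues: int = DEFAULT_MAX_RESIDUES,
    allowed_positions: tuple[int, ...] = DEFAULT_ALLOWED_POSITIONS,
    max_substitutions: int = DEFAULT_MAX_SUBSTITUTIONS,
    screen_edges: list[LinkageEdge] | None = None,
    screen_adjacencies: list[AdjacencyConstraint] | None = None,
) -> list[RepeatUnit] | list[GlycanTree]:
    """All canonical structures over ``composition`` compatible with the
    observed PMAA multiset.

    Compatibility: each observed pattern accounts for exactly one residue
    of a matching sugar name/class; residues not covered by any observed
    pattern must be uronic acids (PMAA cannot see them) and their
    substitution positions are enumerated over ``allowed_positions`` up
    to ``max_substitutions`` sites.

    ``screen_edges`` / ``screen_adjacencies`` optionally apply the
    linkage evidence already during generation — a pure performance
    device used by :class:`StructureElucidator` (structures failing them
    would be pruned immediately afterwards anyway; screening avoids
    canonicalizing them first).  Without these arguments the result
    depends on composition and PMAA alone.
    """
    if not isinstance(composition, Composition):
        composition = Composition(composition)
    if composition.total > max_residues:
        raise ValueError(
            f"composition of {composition.total} residues exceeds the "
            f"configured cap of {max_residues}"
        )
    if isinstance(reducing_class, str):
        reducing_class = SugarClass(reducing_class)
    names = _expand_composition(composition)
    out: dict[str, RepeatUnit | GlycanTree] = {}
    seen_units: set[str] = set()
    from .residues import HYDROXYL_POSITIONS

    screen_edges = screen_edges or []
    screen_adjacencies = screen_adjacencies or []
    for assignment in _pattern_assignments(names, pmaa):
        free_idx = [i for i, (_, p) in enumerate(assignment) if p is None]
        per_residue_choices = [
            list(
                _position_choices(
                    tuple(
                        sorted(
                            set(allowed_positions)
                            & HYDROXYL_POSITIONS[sugar_class_of(assignment[i][0])]
                        )
                    ),
                    max_substitutions,
                )
            )
            for i in free_idx
        ]
        for combo in itertools.product(*per_residue_choices):
            typed = list(assignment)
            for i, pos in zip(free_idx, combo):
                typed[i] = (typed[i][0], pos)
            if (screen_edges or screen_adjacencies) and not _typed_can_host_edges(
                typed, screen_edges, screen_adjacencies
            ):
                continue
            for structure in _enumerate_trees(typed, mode, reducing_class):
                if screen_edges and not all(
                    _satisfies_hmbc(structure, e) for e in screen_edges
                ):
                    continue
                if screen_adjacencies and not all(
                    _satisfies_adjacency(structure, a) for a in screen_adjacencies
                ):
                    continue
                # repeat units are deduplicated as polymers: phase
                # rotations describe the same chain and no observation
                # can tell them apart
                if mode == "repeat":
                    # cheap unit-level dedup first; polymer-level dedup
                    # (phase rotations) only for unseen unit shapes
                    unit_key = structure.canonical_form()
                    if unit_key in seen_units:
                        continue
                    seen_units.add(unit_key)
                    key = structure.polymer_canonical_form()
                    if key not in out:
                        # deterministic representative: the phase whose
                        # canonical string is the polymer canonical
                        out[key] = min(
                            structure.rotations(), key=lambda r: r.canonical_form()
                        )
                else:
                    key = structure.canonical_form()
                    if key not in out:
                        out[key] = structure
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _edge_identities(candidate: RepeatUnit | GlycanTree):
    """(donor name, donor substitutions, position, acceptor name, acceptor
    substitutions) for every bond, the exit bond included; substitution
    sets are polymer-level (the exit counts on the attachment residue)."""
    if isinstance(candidate, RepeatUnit):
        tree = candidate.tree
        sub = candidate.substituted_positions
    else:
        tree = candidate
        sub = tree.substituted_positions
    for child, parent, pos in candidate.edges():
        yield (
            tree.residues[child].name,
            sub(child),
            pos,
            tree.residues[parent].name,
            sub(parent),
        )


def _y_piece_compositions(frag) -> list[Composition]:
    tree = frag.tree
    out = []
    for child, _, _ in tree.edges():
        rest = set(tree.residues) - tree.subtree_ids(child)
        counts: dict[str, int] = {}
        for rid in rest:
            counts[tree.residues[rid].name] = counts.get(tree.residues[rid].name, 0) + 1
        out.append(Composition(counts))
    return out


def _satisfies_fragment(candidate: RepeatUnit, obs: FragmentObservation, cache: dict) -> bool:
    size = obs.composition.total
    key = size
    if key not in cache:
        cache[key] = enumerate_fragments(candidate, size)
    for frag in cache[key]:
        if not frag.composition().matches(obs.composition):
            continue
        root = frag.tree.residues[frag.tree.root_id]
        if not (
            identities_match(obs.reducing_end, root.name)
        ):
            continue
        if obs.b_prefix and not has_linear_nonreducing_prefix(frag, list(obs.b_prefix)):
            continue
        if obs.y_compositions:
            pieces = _y_piece_compositions(frag)
            if not all(
                any(piece.matches(want) for piece in pieces) for want in obs.y_compositions
            ):
                continue
        return True
    return False


def _satisfies_adjacency(candidate, adj: AdjacencyConstraint) -> bool:
    return any(
        identities_match(adj.donor, d) and identities_match(adj.acceptor, a)
        for d, _, _, a, _ in _edge_identities(candidate)
    )


def _satisfies_hmbc(candidate, edge: LinkageEdge) -> bool:
    return any(
        pos == edge.position
        and identities_match(edge.donor, d)
        and identities_match(edge.acceptor, a)
        and (edge.donor_substitutions is None or edge.donor_substitutions == dsub)
        and (edge.acceptor_substitutions is None or edge.acceptor_substitutions == asub)
        for d, dsub, pos, a, asub in _edge_identities(candidate)
    )


def prune(
    candidates: list[RepeatUnit],
    obs: ObservationSet,
    report: "RunReport | None" = None,
) -> list[RepeatUnit]:
    """Keep candidates consistent with every adjacency, HMBC and fragment
    observation.  The constraints are a conjunction, so they are applied
    cheapest first (edge checks before fragment enumeration) and tallied
    per stage."""
    stages: list[tuple[str, object]] = []
    for a in obs.adjacencies:
        stages.append((f"adjacency:{a.donor}->{a.acceptor}", a))
    for e in obs.hmbc:
        stages.append((f"hmbc:{e.donor}-(1->{e.position})-{e.acceptor}", e))
    # small fragments are cheapest to enumerate and often decisive
    for f in sorted(obs.fragments, key=lambda f: f.composition.total):
        stages.append((f"fragment:{f.name}", f))
    current = list(candidates)
    caches: dict[int, dict] = {id(c): {} for c in current}
    for label, constraint in stages:
        before = len(current)
        if isinstance(constraint, FragmentObservation):
            current = [
                c for c in current
                if _satisfies_fragment(c, constraint, caches[id(c)])
            ]
        elif isinstance(constraint, AdjacencyConstraint):
            current = [c for c in current if _satisfies_adjacency(c, constraint)]
        else:
            current = [c for c in current if _satisfies_hmbc(c, constraint)]
        if report is not None:
            report.add_stage(label, before, len(current))
        if not current:
            if report is not None:
                report.first_unsatisfiable = label
            break
    return current


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Per-stage candidate tally of an elucidation run."""

    inputs_digest: str = ""
    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (label, before, after)
    first_unsatisfiable: str | None = None
    wall_time_s: float = 0.0
    version: str = __version__

    def add_stage(self, label: str, before: int, after: int) -> None:
        self.stages.append((label, before, after))

    def to_text(self) -> str:
        lines = [
            f"glycoelucidate {self.version}  observations {self.inputs_digest}",
            f"wall time: {self.wall_time_s:.2f} s",
        ]
        for label, before, after in self.stages:
            lines.append(f"  {label:<45s} {before:>5d} -> {after:>5d}")
        if self.first_unsatisfiable:
            lines.append(f"INCONSISTENT at: {self.first_unsatisfiable}")
        return "\n".join(lines)


class StructureElucidator:
    """Elucidation model over an :class:`ObservationSet`.

    Mirrors the fit interface of statistical modelling packages: the
    model is constructed from data (the observations) plus configuration,
    and :meth:`fit` runs the candidate generation + pruning and returns
    an :class:`ElucidationResults`.
    """

    def __init__(
        self,
        observations: ObservationSet,
        mode: str = "repeat",
        reducing_class: SugarClass | str | None = None,
        max_residues: int = DEFAULT_MAX_RESIDUES,
        allowed_positions: tuple[int, ...] = DEFAULT_ALLOWED_POSITIONS,
        max_substitutions: int = DEFAULT_MAX_SUBSTITUTIONS,
        screen_with_edges: bool = True,
    ):
        self.observations = observations
        self.mode = mode
        self.reducing_class = reducing_class
        self.max_residues = max_residues
        self.allowed_positions = allowed_positions
        self.max_substitutions = max_substitutions
        self.screen_with_edges = screen_with_edges

    @classmethod
    def from_json(cls, path, **kwargs) -> "StructureElucidator":
        from .io import load_observations

        return cls(load_observations(path), **kwargs)

    def fit(self) -> "ElucidationResults":
        t0 = time.perf_counter()
        report = RunReport(inputs_digest=self.observations.digest())
        # linkage evidence is applied already during generation: candidates
        # failing it would be pruned right away, and screening them before
        # canonical deduplication keeps large search spaces tractable
        space = candidate_space(
            self.observations.composition,
            self.observations.pmaa,
            mode=self.mode,
            reducing_class=self.reducing_class,
            max_residues=self.max_residues,
            allowed_positions=self.allowed_positions,
            max_substitutions=self.max_substitutions,
            screen_edges=self.observations.hmbc if self.screen_with_edges else None,
            screen_adjacencies=(
                self.observations.adjacencies if self.screen_with_edges else None
            ),
        )
        label = "candidate space (composition + PMAA{})".format(
            ", linkage-screened" if self.screen_with_edges else ""
        )
        report.add_stage(label, 0, len(space))
        if not space:
            report.first_unsatisfiable = "candidate space (composition + PMAA)"
            survivors = []
        else:
            survivors = prune(space, self.observations, report)
        report.wall_time_s = time.perf_counter() - t0
        return ElucidationResults(model=self, candidates=survivors, report=report)


class ElucidationResults:
    """Outcome of an elucidation run: surviving candidate structures in
    deterministic (canonical) order plus the per-stage run report."""

    def __init__(self, model: StructureElucidator, candidates: list, report: RunReport):
        self.model = model
        self.candidates = candidates
        self.report = report

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def is_unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def is_ambiguous(self) -> bool:
        """More than one structure fits all observations — a genuine
        symmetry of the evidence, not a failure of the search."""
        return len(self.candidates) > 1

    @property
    def is_inconsistent(self) -> bool:
        return len(self.candidates) == 0

    @property
    def structure(self):
        if not self.is_unique:
            raise InconsistentObservations(self.report.first_unsatisfiable or "ambiguous result")
        return self.candidates[0]

    def summary(self) -> str:
        import pandas as pd

        rows = [
            {"stage": label, "candidates before": b, "candidates after": a}
            for label, b, a in self.report.stages
        ]
        table = pd.DataFrame(rows).to_string(index=False)
        status = (
            "unique structure"
            if self.is_unique
            else ("AMBIGUOUS: evidence admits several structures" if self.is_ambiguous else "INCONSISTENT observations")
        )
        head = [
            "Repeat-unit structure elucidation",
            f"  observations: {self.report.inputs_digest}   "
            f"wall time: {self.report.wall_time_s:.2f} s",
            f"  result: {status} ({self.n_candidates} candidate(s))",
        ]
        body = [table, ""]
        for c in self.candidates:
            body.append(f"  {c.canonical_form()}")
        return "\n".join(head + [""] + body)

    def plot_elimination(self, ax=None):
        """Bar chart of remaining candidates after each pruning stage."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        labels = [s[0] for s in self.report.stages]
        after = [s[2] for s in self.report.stages]
        ax.bar(range(len(after)), after)
        ax.set_xticks(range(len(after)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("candidates remaining")
        return ax


def elucidate(
    obs: ObservationSet,
    strict: bool = False,
    **kwargs,
) -> ElucidationResults:
    """Run the full deduction; with ``strict`` an empty result raises
    :class:`InconsistentObservations` naming the first unsatisfiable
    constraint."""
    results = StructureElucidator(obs, **kwargs).fit()
    if strict and results.is_inconsistent:
        raise InconsistentObservations(
            results.report.first_unsatisfiable or "no candidate matches the composition/PMAA"
        )
    return results
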