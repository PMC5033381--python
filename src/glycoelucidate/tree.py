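"""Rooted glycan trees, repeating units, condensed-notation parsing and
canonical serialization.

A :class:`GlycanTree` is a rooted tree of monosaccharide residues.  The
root is the reducing end: every non-root residue donates its anomeric
carbon (position 1, these are all aldopyranoses) to a numbered ring
position of its parent.  A :class:`RepeatUnit` is a glycan tree whose
root's anomeric carbon additionally glycosylates a position on a
designated residue of the *next* copy of the unit, which is how the
polysaccharide chain is generated.

Condensed notation follows carbohydrate convention, written from the
non-reducing end towards the reducing end::

    β-D-Glcp-(1→4)-α-L-6dTalp-(1→4)-α-D-GalpA-(1→4)-D-Galp

Branches are bracketed and bind to the residue that follows them;
repeating units carry a leading ``→n)`` (the position on the *first
written* residue that receives the chain-extending bond) and a trailing
open ``(1→``.  See the README for the full grammar.
"""

from __future__ import annotations

import functools
import itertools
import json
import re
from dataclasses import dataclass, field

from .residues import (
    CATALOG,
    MonosaccharideIdentity,
    SugarClass,
    is_class_token,
    sugar_class_of,
)

VALID_PARENT_POSITIONS = frozenset({2, 3, 4, 5, 6})


@functools.lru_cache(maxsize=4096)
def _token_cached(ident: MonosaccharideIdentity, level: str) -> str:
    return ident.token(level)


class GlycanParseError(ValueError):
    """Raised for malformed condensed-notation input."""


@dataclass(frozen=True)
class Linkage:
    """A glycosidic bond: the child's anomeric C-1 to ``parent_position``."""

    parent_position: int
    child_anomeric_position: int = 1

    def __post_init__(self) -> None:
        if self.parent_position not in VALID_PARENT_POSITIONS:
            raise ValueError(f"parent position must be in 2..6, got {self.parent_position}")
        if self.child_anomeric_position != 1:
            raise ValueError("aldose residues donate from position 1")


class Composition(dict):
    """Residue counts keyed by sugar name or generic class token."""

    def __init__(self, counts: dict[str, int] | None = None, **kw: int):
        super().__init__()
        for k, v in {**(counts or {}), **kw}.items():
            sugar_class_of(k)
            if v < 0:
                raise ValueError("negative residue count")
            if v:
                self[k] = self.get(k, 0) + int(v)

    @property
    def total(self) -> int:
        return sum(self.values())

    def class_counts(self) -> "Composition":
        out: dict[str, int] = {}
        for name, n in self.items():
            key = sugar_class_of(name).value
            out[key] = out.get(key, 0) + n
        return Composition(out)

    def matches(self, observed: "Composition") -> bool:
        """Whether this (fully specified) composition satisfies an observed
        one whose keys may mix names and class tokens.

        A class-token key in ``observed`` consumes residues of that class
        that are not already claimed by name-level keys.
        """
        if self.total != observed.total:
            return False
        by_name = dict(self)
        for key, need in observed.items():
            if is_class_token(key):
                continue
            if by_name.get(key, 0) < need:
                return False
            by_name[key] -= need
        for key, need in observed.items():
            if not is_class_token(key):
                continue
            avail = sum(
                n for name, n in by_name.items() if sugar_class_of(name) == sugar_class_of(key)
            )
            if avail < need:
                return False
        return True


@dataclass
class GlycanTree:
    """Rooted tree of residues; the root is the reducing end."""

    residues: dict[str, MonosaccharideIdentity]
    parent: dict[str, tuple[str, Linkage]]  # child id -> (parent id, linkage)
    root_id: str

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def _trusted(cls, residues, parent, root_id) -> "GlycanTree":
        """Construction bypassing validation, for internal call sites that
        build trees known to be valid (hot paths: enumeration, chaining)."""
        obj = object.__new__(cls)
        obj.residues = residues
        obj.parent = parent
        obj.root_id = root_id
        return obj

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if self.root_id not in self.residues:
            raise ValueError("root id not among residues")
        if self.root_id in self.parent:
            raise ValueError("root must not have a parent")
        for child, (par, _) in self.parent.items():
            if child not in self.residues or par not in self.residues:
                raise ValueError(f"edge {child}->{par} references unknown residue")
        if set(self.parent) != set(self.residues) - {self.root_id}:
            raise ValueError("every non-root residue needs exactly one parent")
        # acyclicity / connectivity: walk up from every node
        for node in self.residues:
            seen = set()
            while node != self.root_id:
                if node in seen:
                    raise ValueError("cycle detected")
                seen.add(node)
                node = self.parent[node][0]
        for rid in self.residues:
            positions = [l.parent_position for (p, l) in self.parent.values() if p == rid]
            if len(positions) != len(set(positions)):
                raise ValueError(f"residue {rid} substituted twice at one position")
            bad = set(positions) - self.residues[rid].hydroxyl_positions
            if bad:
                raise ValueError(
                    f"residue {rid} ({self.residues[rid].name}) has no hydroxyl at {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def children(self, rid: str) -> list[tuple[str, int]]:
        """(child id, parent position) pairs, sorted by position."""
        out = [(c, l.parent_position) for c, (p, l) in self.parent.items() if p == rid]
        return sorted(out, key=lambda t: t[1])

    def substituted_positions(self, rid: str) -> frozenset[int]:
        return frozenset(pos for _, pos in self.children(rid))

    def edges(self) -> list[tuple[str, str, int]]:
        """(child, parent, parent position) for every glycosidic bond."""
        return [(c, p, l.parent_position) for c, (p, l) in self.parent.items()]

    def subtree_ids(self, rid: str) -> set[str]:
        out, stack = set(), [rid]
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(c for c, _ in self.children(n))
        return out

    def subtree(self, rid: str) -> "GlycanTree":
        ids = self.subtree_ids(rid)
        return GlycanTree._trusted(
            residues={i: self.residues[i] for i in ids},
            parent={c: pl for c, pl in self.parent.items() if c in ids and c != rid},
            root_id=rid,
        )

    def induced(self, ids: set[str]) -> "GlycanTree":
        """Tree induced by a connected, parent-closed-towards-its-top id set.

        The residue of ``ids`` closest to the tree root becomes the new
        root (its anomeric bond is the one that was cleaved).
        """
        tops = [i for i in ids if i == self.root_id or self.parent[i][0] not in ids]
        if len(tops) != 1:
            raise ValueError("id set is not connected")
        return GlycanTree._trusted(
            residues={i: self.residues[i] for i in ids},
            parent={c: pl for c, pl in self.parent.items() if c in ids and c != tops[0]},
            root_id=tops[0],
        )

    # -- derived data ------------------------------------------------------
    def composition(self, level: str = "name") -> Composition:
        counts: dict[str, int] = {}
        for ident in self.residues.values():
            key = ident.sugar_class.value if level == "class" else ident.name
            counts[key] = counts.get(key, 0) + 1
        return Composition(counts)

    # -- canonical form ----------------------------------------------------
    def _render(
        self, rid: str, level: str, chain_child: dict[str, str | None] | None = None
    ) -> str:
        """Condensed string of the subtree rooted at ``rid``.

        Children are ordered by (parent position, rendered subtree); the
        first child continues the main chain, the rest are bracketed.
        ``chain_child`` routes a repeat unit's backbone: it forces a
        particular child onto the main chain, and ``None`` for a node
        (the attachment residue) brackets *all* its children so the node
        itself is written leftmost, where the leading ``→n)`` binds.
        """
        child_map: dict[str, list[tuple[str, int]]] = {r: [] for r in self.residues}
        for c, (p, l) in self.parent.items():
            child_map[p].append((c, l.parent_position))

        def render(node: str) -> str:
            token = _token_cached(self.residues[node], level)
            kids = child_map[node]
            if not kids:
                return token
            rendered = sorted(
                ((render(c), pos, c) for c, pos in kids), key=lambda t: (t[1], t[0])
            )
            if chain_child and node in chain_child:
                if chain_child[node] is None:
                    branches = "".join(f"[{s}-(1→{p})]-" for s, p, _ in rendered)
                    return f"{branches}{token}"
                rendered.sort(key=lambda t: t[2] != chain_child[node])
            head, pos0, _ = rendered[0]
            branches = "".join(f"[{s}-(1→{p})]-" for s, p, _ in rendered[1:])
            return f"{head}-(1→{pos0})-{branches}{token}"

        return render(rid)

    def canonical_form(self, level: str = "full") -> str:
        """Deterministic condensed string; isomorphic trees map to equal
        strings under any residue-id relabeling."""
        return self._render(self.root_id, level)

    def relabel(self, mapping: dict[str, str]) -> "GlycanTree":
        return GlycanTree(
            residues={mapping[i]: r for i, r in self.residues.items()},
            parent={mapping[c]: (mapping[p], l) for c, (p, l) in self.parent.items()},
            root_id=mapping[self.root_id],
        )

    def strip_attrs(self) -> "GlycanTree":
        return GlycanTree(
            residues={i: r.strip_attrs() for i, r in self.residues.items()},
            parent=dict(self.parent),
            root_id=self.root_id,
        )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "residues": {
                i: {
                    "name": r.name,
                    "absolute_config": r.absolute_config,
                    "anomeric_config": r.anomeric_config,
                }
                for i, r in self.residues.items()
            },
            "edges": [
                {"child": c, "parent": p, "position": l.parent_position}
                for c, (p, l) in self.parent.items()
            ],
            "root": self.root_id,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GlycanTree":
        residues = {
            i: MonosaccharideIdentity(
                d["name"],
                absolute_config=d.get("absolute_config", "unknown"),
                anomeric_config=d.get("anomeric_config", "unknown"),
            )
            for i, d in obj["residues"].items()
        }
        parent = {
            e["child"]: (e["parent"], Linkage(e["position"])) for e in obj["edges"]
        }
        return cls(residues=residues, parent=parent, root_id=obj["root"])


@dataclass
class RepeatUnit:
    """A repeating unit: a glycan tree rooted at the residue whose anomeric
    carbon *exits* the unit, plus the exit linkage.

    ``exit_attachment`` names the residue (of the adjacent copy) and the
    position on it that the root glycosylates when units are chained.
    """

    tree: GlycanTree
    exit_attachment: tuple[str, int]  # (residue id, parent position)

    def __post_init__(self) -> None:
        rid, pos = self.exit_attachment
        if rid not in self.tree.residues:
            raise ValueError("exit attachment residue not in tree")
        if pos not in self.tree.residues[rid].hydroxyl_positions:
            raise ValueError(f"no hydroxyl at position {pos} on {self.tree.residues[rid].name}")
        if pos in self.tree.substituted_positions(rid):
            raise ValueError("exit attachment position already substituted intra-unit")

    @classmethod
    def _trusted(cls, tree, exit_attachment) -> "RepeatUnit":
        obj = object.__new__(cls)
        obj.tree = tree
        obj.exit_attachment = exit_attachment
        return obj

    def __len__(self) -> int:
        return len(self.tree)

    def composition(self, level: str = "name") -> Composition:
        return self.tree.composition(level)

    def substituted_positions(self, rid: str) -> frozenset[int]:
        """Intra-unit substitutions plus the exit attachment."""
        pos = set(self.tree.substituted_positions(rid))
        if rid == self.exit_attachment[0]:
            pos.add(self.exit_attachment[1])
        return frozenset(pos)

    def edges(self) -> list[tuple[str, str, int]]:
        """All linkages of the polymer, the exit bond included (the exit is
        reported as root -> attachment residue, wrapping into the next copy)."""
        out = self.tree.edges()
        out.append((self.tree.root_id, self.exit_attachment[0], self.exit_attachment[1]))
        return out

    def canonical_form(self, level: str = "full") -> str:
        att, pos = self.exit_attachment
        root = self.tree.root_id
        if att == root and len(self.tree) > 1:
            # attachment on the root itself cannot be written leftmost;
            # a starred head marks "attaches to the rightmost residue"
            return f"→{pos}*)-{self.tree._render(root, level)}-(1→"
        chain_child: dict[str, str | None] = {att: None}
        node = att
        while node != root:
            par = self.tree.parent[node][0]
            chain_child[par] = node
            node = par
        return f"→{pos})-{self.tree._render(root, level, chain_child)}-(1→"

    def chain(self, k: int) -> GlycanTree:
        """Materialize ``k`` chained copies as one glycan tree.

        Copy ``k-1`` (suffix ``/k-1``) holds the overall reducing end; the
        root of each earlier copy glycosylates the attachment residue of
        the next copy.  The result has ``k*n`` residues and ``k*n - 1``
        edges for an ``n``-residue unit.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        residues: dict[str, MonosaccharideIdentity] = {}
        parent: dict[str, tuple[str, Linkage]] = {}
        att, pos = self.exit_attachment
        for i in range(k):
            tag = f"/{i}"
            for rid, ident in self.tree.residues.items():
                residues[rid + tag] = ident
            for c, (p, l) in self.tree.parent.items():
                parent[c + tag] = (p + tag, l)
            if i > 0:
                parent[self.tree.root_id + f"/{i-1}"] = (att + tag, Linkage(pos))
        return GlycanTree._trusted(
            residues=residues, parent=parent, root_id=self.tree.root_id + f"/{k-1}"
        )

    @property
    def backbone_length(self) -> int:
        """Residues on the backbone cycle (attachment → root → exit).

        This is the polymer's true repeat period along the main chain;
        it is shorter than the unit size when residues sit on side
        chains."""
        att = self.exit_attachment[0]
        length = 1
        node = att
        while node != self.tree.root_id:
            node = self.tree.parent[node][0]
            length += 1
        return length

    def rotations(self) -> list["RepeatUnit"]:
        """All phase rotations of this unit: the same infinite polymer cut
        at each backbone-cycle bond.

        The backbone cycle runs from the attachment residue up to the
        root and closes through the exit bond.  Cutting any of its bonds
        yields an equally valid repeat unit of the same polymer; no
        composition/linkage/MS observation can distinguish them.
        """
        att, exit_pos = self.exit_attachment
        root = self.tree.root_id
        path: list[str] = [att]
        while path[-1] != root:
            path.append(self.tree.parent[path[-1]][0])
        out = [self]
        for child, parent_id in zip(path, path[1:]):
            link = self.tree.parent[child][1]
            new_parent = {
                c: pl for c, pl in self.tree.parent.items() if c != child
            }
            new_parent[root] = (att, Linkage(exit_pos))
            new_tree = GlycanTree._trusted(
                residues=self.tree.residues, parent=new_parent, root_id=child
            )
            out.append(
                RepeatUnit._trusted(new_tree, (parent_id, link.parent_position))
            )
        return out

    def polymer_canonical_form(self, level: str = "full") -> str:
        """Canonical string of the *polymer*: the minimum canonical form
        over all phase rotations."""
        return min(r.canonical_form(level) for r in self.rotations())

    def relabel(self, mapping: dict[str, str]) -> "RepeatUnit":
        return RepeatUnit(
            tree=self.tree.relabel(mapping),
            exit_attachment=(mapping[self.exit_attachment[0]], self.exit_attachment[1]),
        )

    def strip_attrs(self) -> "RepeatUnit":
        return RepeatUnit(tree=self.tree.strip_attrs(), exit_attachment=self.exit_attachment)

    def to_json(self) -> dict:
        obj = self.tree.to_json()
        obj["exit"] = {"residue": self.exit_attachment[0], "position": self.exit_attachment[1]}
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "RepeatUnit":
        return cls(
            tree=GlycanTree.from_json(obj),
            exit_attachment=(obj["exit"]["residue"], obj["exit"]["position"]),
        )


# ---------------------------------------------------------------------------
# condensed-notation parser
# ---------------------------------------------------------------------------

def _name_forms() -> dict[str, str]:
    """surface form -> catalog name (ring letter folded in, e.g. GalpA)."""
    forms: dict[str, str] = {}
    for name in CATALOG:
        forms[name] = name
        if name.endswith("A"):
            forms[name[:-1] + "pA"] = name
        else:
            forms[name + "p"] = name
    return forms


_NAME_FORMS = _name_forms()
_NAME_RE = "|".join(sorted((re.escape(f) for f in _NAME_FORMS), key=len, reverse=True))
_ARROW = r"(?:→|->)"
_RESIDUE_RE = re.compile(
    rf"(?:(α|β|a|b|alpha|beta)-)?(?:([DL])-)?({_NAME_RE})(?![A-Za-z])"
)
_LINK_RE = re.compile(rf"\(1{_ARROW}([2-6])\)")
_OPEN_EXIT_RE = re.compile(rf"\(1{_ARROW}\s*$")
_HEAD_RE = re.compile(rf"^{_ARROW}([2-6])(\*?)\)-")

_ANOMER = {"α": "alpha", "a": "alpha", "alpha": "alpha", "β": "beta", "b": "beta", "beta": "beta"}


def _tokenize(text: str) -> list:
    """Token stream: ('res', identity) | ('link', pos) | '[' | ']' | ('exit',)."""
    tokens: list = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in "-– ":
            i += 1
            continue
        if ch in "[]":
            tokens.append(ch)
            i += 1
            continue
        if ch == "(":
            m = _LINK_RE.match(text, i)
            if m:
                tokens.append(("link", int(m.group(1))))
                i = m.end()
                continue
            if _OPEN_EXIT_RE.match(text, i):
                tokens.append(("exit",))
                i = n
                continue
            raise GlycanParseError(f"malformed linkage token at ...{text[i:i+12]!r}")
        m = _RESIDUE_RE.match(text, i)
        if m:
            anomer, config, nameform = m.groups()
            ident = MonosaccharideIdentity(
                _NAME_FORMS[nameform],
                absolute_config=config or "unknown",
                anomeric_config=_ANOMER[anomer] if anomer else "unknown",
            )
            tokens.append(("res", ident))
            i = m.end()
            continue
        raise GlycanParseError(f"unrecognized token at ...{text[i:i+15]!r}")
    return tokens


class _Builder:
    def __init__(self) -> None:
        self.counter = itertools.count()
        self.residues: dict[str, MonosaccharideIdentity] = {}
        self.parent: dict[str, tuple[str, Linkage]] = {}

    def new(self, ident: MonosaccharideIdentity) -> str:
        rid = f"r{next(self.counter)}"
        self.residues[rid] = ident
        return rid


def _parse_chain(tokens: list, i: int, builder: _Builder, depth: int) -> tuple[int, str, str, int | None]:
    """Parse a chain; returns (next index, first residue id, last residue id,
    trailing dangling position or None).

    Inside brackets a chain ends with a full linkage whose acceptor is the
    residue following the bracket; that position is returned as dangling.
    """
    pending: list[tuple[str, int]] = []  # (sub-chain root id, its link position)
    first_id = last_id = None
    dangling: int | None = None
    while i < len(tokens):
        tok = tokens[i]
        if tok == "]":
            if depth == 0:
                raise GlycanParseError("unbalanced ']'")
            break
        if tok == "[":
            j, b_first, b_last, b_dangling = _parse_chain(tokens, i + 1, builder, depth + 1)
            if tokens[j : j + 1] != ["]"]:
                raise GlycanParseError("unbalanced '['")
            if b_dangling is None:
                raise GlycanParseError("branch must end with a linkage such as '(1→2)'")
            pending.append((b_last, b_dangling))
            i = j + 1
            continue
        if isinstance(tok, tuple) and tok[0] == "res":
            if dangling is not None:
                # residue follows a completed linkage of the previous residue
                pending.append((last_id, dangling))
                dangling = None
            rid = builder.new(tok[1])
            for child, pos in pending:
                if pos in {l.parent_position for (p, l) in builder.parent.values() if p == rid}:
                    raise GlycanParseError(f"duplicate substitution at position {pos}")
                builder.parent[child] = (rid, Linkage(pos))
            pending = []
            if first_id is None:
                first_id = rid
            last_id = rid
            i += 1
            continue
        if isinstance(tok, tuple) and tok[0] == "link":
            if last_id is None or dangling is not None:
                raise GlycanParseError("linkage token without a donor residue")
            dangling = tok[1]
            i += 1
            continue
        if isinstance(tok, tuple) and tok[0] == "exit":
            raise GlycanParseError("'(1→' is only valid at the end of a repeat unit")
        raise GlycanParseError(f"unexpected token {tok!r}")
    if first_id is None:
        raise GlycanParseError("empty chain")
    if pending:
        raise GlycanParseError("branch not attached to any residue")
    return i, first_id, last_id, dangling


def parse_condensed(text: str) -> GlycanTree | RepeatUnit:
    """Parse condensed notation into a :class:`GlycanTree`, or into a
    :class:`RepeatUnit` when the string carries the repeat markers
    (leading ``→n)`` and trailing ``(1→``)."""
    text = text.strip()
    head = _HEAD_RE.match(text)
    attach_pos: int | None = None
    attach_root = False
    if head:
        attach_pos = int(head.group(1))
        attach_root = head.group(2) == "*"
        text = text[head.end():]
    tokens = _tokenize(text)
    is_repeat = bool(tokens) and tokens[-1] == ("exit",)
    if is_repeat:
        tokens = tokens[:-1]
    if is_repeat != (attach_pos is not None):
        raise GlycanParseError("repeat units need both a leading '→n)' and a trailing '(1→'")
    builder = _Builder()
    i, first_id, last_id, dangling = _parse_chain(tokens, 0, builder, 0)
    if i != len(tokens):
        raise GlycanParseError("unbalanced ']'")
    if dangling is not None:
        raise GlycanParseError("chain ends with an unattached linkage")
    tree = GlycanTree(residues=builder.residues, parent=builder.parent, root_id=last_id)
    if not is_repeat:
        return tree
    attachment = last_id if attach_root else first_id
    return RepeatUnit(tree=tree, exit_attachment=(attachment, attach_pos))


def canonical_form(structure: GlycanTree | RepeatUnit, level: str = "full") -> str:
    return structure.canonical_form(level)


def composition_of(structure: GlycanTree | RepeatUnit, level: str = "name") -> Composition:
    return structure.composition(level)


def isomorphic(a, b, level: str = "full") -> bool:
    """Structural equality under residue-id relabeling."""
    if type(a) is not type(b):
        return False
    return a.canonical_form(level) == b.canonical_form(level)


def same_polymer(a: RepeatUnit, b: RepeatUnit, level: str = "full") -> bool:
    """Whether two repeat units generate the same infinite polymer (equal
    up to residue relabeling *and* phase rotation)."""
    return a.polymer_canonical_form(level) == b.polymer_canonical_form(level)


def dumps(structure: GlycanTree | RepeatUnit) -> str:
    return json.dumps(structure.to_json(), indent=2, sort_keys=True)
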