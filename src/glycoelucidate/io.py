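"""Observation-file schema (JSON) and validation.

One file holds one observation set::

    {
      "composition": {"Glc": 2, "Gal": 2, "GalA": 1, "6dTal": 1},
      "pmaa": [{"sugar": "Glc", "positions": [], "detectable": true}, ...],
      "fragments": [{"name": "os211",
                     "composition": {"Hex": 2, "HexA": 1, "dHex": 1},
                     "reducing_end": "Hex",
                     "b_prefix": ["Hex", "dHex"]}, ...],
      "adjacencies": [{"donor": "HexA", "acceptor": "Hex"}],
      "hmbc": [{"donor": "Glc", "position": 4, "acceptor": "6dTal"}, ...]
    }

Validation failures carry a JSON-pointer-style path to the offending
element (e.g. ``/pmaa/3/positions``).
"""

from __future__ import annotations

import json
from pathlib import Path

from .elucidate import (
    AdjacencyConstraint,
    FragmentObservation,
    LinkageEdge,
    ObservationSet,
    PMAAPattern,
)
from .residues import CATALOG
from .tree import Composition


class ObservationSchemaError(ValueError):
    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def _require(cond: bool, pointer: str, message: str) -> None:
    if not cond:
        raise ObservationSchemaError(pointer, message)


def _sugar(token, pointer: str) -> str:
    _require(isinstance(token, str), pointer, "sugar token must be a string")
    _require(token in CATALOG, pointer, f"unknown sugar token {token!r}")
    return token


def _composition(obj, pointer: str) -> Composition:
    _require(isinstance(obj, dict) and obj, pointer, "composition must be a non-empty object")
    counts = {}
    for key, val in obj.items():
        _sugar(key, f"{pointer}/{key}")
        _require(
            isinstance(val, int) and val >= 1, f"{pointer}/{key}", "count must be a positive integer"
        )
        counts[key] = val
    return Composition(counts)


def parse_observations(obj: dict) -> ObservationSet:
    _require(isinstance(obj, dict), "", "observation file must hold a JSON object")
    _require("composition" in obj, "/composition", "missing required field")
    composition = _composition(obj["composition"], "/composition")

    pmaa = []
    for i, p in enumerate(obj.get("pmaa", [])):
        ptr = f"/pmaa/{i}"
        _require(isinstance(p, dict), ptr, "pattern must be an object")
        _require("sugar" in p, f"{ptr}/sugar", "missing required field")
        _require("positions" in p, f"{ptr}/positions", "missing required field")
        positions = p["positions"]
        _require(
            isinstance(positions, list) and all(isinstance(x, int) for x in positions),
            f"{ptr}/positions",
            "positions must be a list of integers",
        )
        try:
            pmaa.append(
                PMAAPattern(
                    sugar=_sugar(p["sugar"], f"{ptr}/sugar"),
                    positions=frozenset(positions),
                    detectable=bool(p.get("detectable", True)),
                    abundance=p.get("abundance"),
                )
            )
        except ValueError as err:
            raise ObservationSchemaError(ptr, str(err)) from None

    fragments = []
    for i, f in enumerate(obj.get("fragments", [])):
        ptr = f"/fragments/{i}"
        _require(isinstance(f, dict), ptr, "fragment observation must be an object")
        for fld in ("name", "composition", "reducing_end"):
            _require(fld in f, f"{ptr}/{fld}", "missing required field")
        try:
            fragments.append(
                FragmentObservation(
                    name=str(f["name"]),
                    composition=_composition(f["composition"], f"{ptr}/composition"),
                    reducing_end=_sugar(f["reducing_end"], f"{ptr}/reducing_end"),
                    b_prefix=tuple(
                        _sugar(s, f"{ptr}/b_prefix/{j}")
                        for j, s in enumerate(f.get("b_prefix", []))
                    ),
                    y_compositions=tuple(
                        _composition(c, f"{ptr}/y_compositions/{j}")
                        for j, c in enumerate(f.get("y_compositions", []))
                    ),
                )
            )
        except ObservationSchemaError:
            raise
        except ValueError as err:
            raise ObservationSchemaError(ptr, str(err)) from None

    adjacencies = []
    for i, a in enumerate(obj.get("adjacencies", [])):
        ptr = f"/adjacencies/{i}"
        _require(isinstance(a, dict), ptr, "adjacency must be an object")
        for fld in ("donor", "acceptor"):
            _require(fld in a, f"{ptr}/{fld}", "missing required field")
        adjacencies.append(
            AdjacencyConstraint(
                donor=_sugar(a["donor"], f"{ptr}/donor"),
                acceptor=_sugar(a["acceptor"], f"{ptr}/acceptor"),
            )
        )

    hmbc = []
    for i, e in enumerate(obj.get("hmbc", [])):
        ptr = f"/hmbc/{i}"
        _require(isinstance(e, dict), ptr, "hmbc edge must be an object")
        for fld in ("donor", "position", "acceptor"):
            _require(fld in e, f"{ptr}/{fld}", "missing required field")
        _require(isinstance(e["position"], int), f"{ptr}/position", "position must be an integer")

        def _subs(key):
            if key not in e or e[key] is None:
                return None
            val = e[key]
            _require(
                isinstance(val, list) and all(isinstance(x, int) for x in val),
                f"{ptr}/{key}",
                "substitutions must be a list of integers",
            )
            return frozenset(val)

        try:
            hmbc.append(
                LinkageEdge(
                    donor=_sugar(e["donor"], f"{ptr}/donor"),
                    position=e["position"],
                    acceptor=_sugar(e["acceptor"], f"{ptr}/acceptor"),
                    donor_substitutions=_subs("donor_substitutions"),
                    acceptor_substitutions=_subs("acceptor_substitutions"),
                )
            )
        except ValueError as err:
            raise ObservationSchemaError(ptr, str(err)) from None

    return ObservationSet(
        composition=composition,
        pmaa=pmaa,
        fragments=fragments,
        adjacencies=adjacencies,
        hmbc=hmbc,
    )


def load_observations(path) -> ObservationSet:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as err:
            raise ObservationSchemaError("", f"not valid JSON: {err}") from None
    return parse_observations(obj)


def dump_observations(obs: ObservationSet, path=None) -> str:
    obj = {
        "composition": dict(sorted(obs.composition.items())),
        "pmaa": [
            {
                "sugar": p.sugar,
                "positions": sorted(p.positions),
                "detectable": p.detectable,
                **({"abundance": p.abundance} if p.abundance is not None else {}),
            }
            for p in obs.pmaa
        ],
        "fragments": [
            {
                "name": f.name,
                "composition": dict(sorted(f.composition.items())),
                "reducing_end": f.reducing_end,
                **({"b_prefix": list(f.b_prefix)} if f.b_prefix else {}),
                **(
                    {"y_compositions": [dict(sorted(c.items())) for c in f.y_compositions]}
                    if f.y_compositions
                    else {}
                ),
            }
            for f in obs.fragments
        ],
        "adjacencies": [{"donor": a.donor, "acceptor": a.acceptor} for a in obs.adjacencies],
        "hmbc": [
            {
                "donor": e.donor,
                "position": e.position,
                "acceptor": e.acceptor,
                **(
                    {"donor_substitutions": sorted(e.donor_substitutions)}
                    if e.donor_substitutions is not None
                    else {}
                ),
                **(
                    {"acceptor_substitutions": sorted(e.acceptor_substitutions)}
                    if e.acceptor_substitutions is not None
                    else {}
                ),
            }
            for e in obs.hmbc
        ],
    }
    text = json.dumps(obj, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
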