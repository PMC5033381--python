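"""Data-level NMR utilities: chemical-shift tables, anomeric-signal
counting, HMBC-correlation graphs and structure-consistency checks.

No spectral processing happens here.  The inputs are assigned shift
tables (per residue label and ring position) and lists of inter-residue
HMBC correlations; the outputs are the counting and consistency
arguments that support a repeat-unit assignment: the number of anomeric
signals fixes the repeat-unit size, and H-1(i)→C-n(j) correlations read
directly as glycosidic bonds i-(1→n)-j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .tree import GlycanTree, RepeatUnit

POSITIONS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class HMBCCorrelation:
    """A long-range H→C correlation between (residue, proton position) and
    (residue, carbon position)."""

    from_residue: str
    proton_position: int
    to_residue: str
    carbon_position: int

    def __post_init__(self) -> None:
        for p in (self.proton_position, self.carbon_position):
            if p not in POSITIONS:
                raise ValueError("positions must be in 1..6")


@dataclass(frozen=True)
class LabelledEdge:
    """A glycosidic bond between labelled residues: donor-(1→position)-acceptor."""

    donor: str
    position: int
    acceptor: str


class NMRTable:
    """Per-residue, per-position ¹H/¹³C chemical shifts.

    Backed by a DataFrame with columns ``residue`` (label, e.g. A–F),
    ``identity`` (condensed residue token), ``nucleus`` (H or C), ``P1``…
    ``P6`` (shifts in ppm, blank where unassigned) and ``ambiguity``
    (free-text flag for assignments that may be interchanged).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"residue", "nucleus"} | {f"P{i}" for i in POSITIONS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"shift table lacks columns {sorted(missing)}")
        for i in POSITIONS:
            frame[f"P{i}"] = pd.to_numeric(frame[f"P{i}"], errors="coerce")
        bad_h = frame.loc[frame.nucleus == "H", [f"P{i}" for i in POSITIONS]]
        if ((bad_h < 0) | (bad_h > 12)).any().any():
            raise ValueError("proton shifts must lie in 0..12 ppm")
        bad_c = frame.loc[frame.nucleus == "C", [f"P{i}" for i in POSITIONS]]
        if ((bad_c < 0) | (bad_c > 220)).any().any():
            raise ValueError("carbon shifts must lie in 0..220 ppm")
        dup = frame.duplicated(subset=["residue", "nucleus"])
        if dup.any():
            raise ValueError("duplicate (residue, nucleus) rows")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path=None) -> "NMRTable":
        """Load a shift table; with no path, the packaged table of the
        B. longum 35624 exopolysaccharide assignments."""
        if path is None:
            ref = resources.files("glycoelucidate.data") / "eps35624_shifts.csv"
            with ref.open() as fh:
                frame = pd.read_csv(fh)
        else:
            frame = pd.read_csv(path)
        return cls(frame)

    def shift(self, residue: str, nucleus: str, position: int) -> float | None:
        row = self.frame[(self.frame.residue == residue) & (self.frame.nucleus == nucleus)]
        if row.empty:
            return None
        val = row.iloc[0][f"P{position}"]
        return None if pd.isna(val) else float(val)

    def identity_of(self, residue: str) -> str | None:
        row = self.frame[self.frame.residue == residue]
        if row.empty or "identity" not in self.frame.columns:
            return None
        return str(row.iloc[0]["identity"])

    def residues(self) -> list[str]:
        return sorted(self.frame.residue.unique())


def count_anomeric_signals(
    table: NMRTable, nucleus: str, window: tuple[float, float]
) -> int:
    """Number of distinct anomeric (position-1) *signals* inside the closed
    ppm window.

    Signals, not residues: shifts identical at 2-decimal precision
    coincide in the spectrum and count once (their multiplicity is
    recoverable via :func:`anomeric_signal_multiplicities`).
    """
    return len(anomeric_signal_multiplicities(table, nucleus, window))


def anomeric_signal_multiplicities(
    table: NMRTable, nucleus: str, window: tuple[float, float]
) -> dict[float, int]:
    """Map signal position (ppm, 2 decimals) → number of coinciding
    anomeric resonances within the window."""
    if nucleus not in ("H", "C"):
        raise ValueError("nucleus must be 'H' or 'C'")
    lo, hi = window
    if table.frame.empty:
        raise ValueError("empty shift table")
    out: dict[float, int] = {}
    for residue in table.residues():
        val = table.shift(residue, nucleus, 1)
        if val is None:
            continue
        val = round(val, 2)
        if lo <= val <= hi:
            out[val] = out.get(val, 0) + 1
    return out


def hmbc_to_edges(correlations: list[HMBCCorrelation]) -> list[LabelledEdge]:
    """Read glycosidic bonds out of inter-residue HMBC correlations.

    A correlation with an anomeric terminus on either side becomes the
    directed edge donor-(1→n)-acceptor (direction normalized so the
    anomeric side donates); intra-residue correlations and correlations
    with no anomeric terminus are skipped.  Idempotent under duplicates.
    """
    edges: list[LabelledEdge] = []
    seen: set[tuple] = set()
    for corr in correlations:
        if corr.from_residue == corr.to_residue:
            continue
        if corr.proton_position == 1:
            edge = LabelledEdge(corr.from_residue, corr.carbon_position, corr.to_residue)
        elif corr.carbon_position == 1:
            edge = LabelledEdge(corr.to_residue, corr.proton_position, corr.from_residue)
        else:
            import warnings

            warnings.warn(
                f"correlation {corr} has no anomeric terminus; skipped", stacklevel=2
            )
            continue
        key = (edge.donor, edge.position, edge.acceptor)
        if key not in seen:
            seen.add(key)
            edges.append(edge)
    return edges


@dataclass
class HMBCReport:
    """Outcome of checking a structure against HMBC-derived bonds."""

    confirmed: list[LabelledEdge] = field(default_factory=list)
    uncovered: list[LabelledEdge] = field(default_factory=list)
    contradicting: list[LabelledEdge] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.contradicting


def check_structure_vs_hmbc(
    structure: RepeatUnit | GlycanTree,
    correlations: list[HMBCCorrelation],
    labels: dict[str, str],
) -> HMBCReport:
    """Compare a structure's linkage graph with HMBC-derived bonds.

    ``labels`` maps residue labels (as used in the correlations) to
    residue ids of the structure.  The repeat unit's exit bond counts as
    a structure edge (it wraps onto the attachment residue).  The report
    lists bonds confirmed by a correlation, structure bonds no
    correlation covers, and correlations contradicting the structure.
    """
    tree = structure.tree if isinstance(structure, RepeatUnit) else structure
    id_of = dict(labels)
    label_of = {v: k for k, v in id_of.items()}
    structure_edges = {
        (label_of[c], pos, label_of[p]) for c, p, pos in structure.edges()
    }
    observed = hmbc_to_edges(correlations)
    observed_keys = set()
    report = HMBCReport()
    for edge in observed:
        if edge.donor not in id_of or edge.acceptor not in id_of:
            raise KeyError(f"correlation references unknown residue label in {edge}")
        key = (edge.donor, edge.position, edge.acceptor)
        observed_keys.add(key)
        if key in structure_edges:
            report.confirmed.append(edge)
        else:
            report.contradicting.append(edge)
    for key in sorted(structure_edges - observed_keys):
        report.uncovered.append(LabelledEdge(*key))
    return report
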