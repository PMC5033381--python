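# Methods

## Scope and model

The package executes the deductive core of a classical polysaccharide
structure determination.  The object of inference is the repeating unit
of a bacterial exopolysaccharide: a rooted tree of aldopyranose residues
in which every non-root residue donates its anomeric carbon (C-1) to a
ring position (2, 3, 4 or 6) of its parent, plus an *exit* bond through
which the root's anomeric carbon glycosylates a designated position on
the next copy of the unit.  Furanoses, ring-conformation and 3D
stereochemistry are out of scope; residues are identified by a name
token (Glc, Gal, GalA, 6dTal, …) with sugar class (Hex / dHex / HexA)
and optional D/L and α/β attributes.  O-acetylation can be recorded on a
residue but is never inferred: mild acid de-acetylates the polymer
before every measurement the solver consumes, so no observation channel
carries acetyl information.

## Evidence channels and their semantics

All evidence is treated as qualitative presence calls, matching how the
wet-lab channels actually behave:

* **Composition** — exact residue counts (name- or class-level).  The
  published molar ratios behind them (detector-response weighted) are
  stored but never used quantitatively.
* **PMAA linkage patterns** — per residue, the set of glycosylated ring
  positions.  Uronic acids are invisible to permethylation analysis, so
  a candidate may carry uronic residues with *any* substitution pattern
  not present in the observations; every observed pattern, conversely,
  must be accounted for by exactly one residue.  For a repeat unit the
  exit bond counts as a substitution on the attachment residue.
  Abundances are stored as data only.
* **Hydrolysis fragments** — acid hydrolysis is modelled as cleavage of
  an arbitrary bond subset without kinetic weighting, so the fragment
  universe of a candidate is every connected subtree of the chained
  polymer, deduplicated structurally (MS cannot see chain translation).
  An observation carries a composition, the reducing-end sugar class
  (from borodeuteride labelling), optionally a b-ion sequence read from
  the non-reducing terminus and the compositions of reducing-side
  single-cleavage (y) pieces.  A candidate satisfies the observation if
  *one* of its fragments explains all of these simultaneously — the y
  series is what localizes a branch relative to the reducing end.
  Observed isomer counts per mass are *not* used as constraints: the
  number of chromatographic peaks reflects chromatography, not topology.
* **Adjacencies** — an acid-stable aldobiuronic disaccharide implies a
  HexA→Hex bond somewhere in the polymer (position unconstrained).
* **HMBC bonds** — an inter-residue correlation with an anomeric
  terminus on either side reads as a glycosidic bond donor-(1→n)-acceptor.
  Where the NMR assignment has also established the residues'
  glycosylation patterns (via glycosylation shifts), the bond may carry
  those patterns as a refinement; this is what distinguishes two
  same-name residues with different linkage roles, e.g. a →4)-Gal from
  the →2,4)-Gal branch point.

## The solver

`candidate_space(composition, pmaa)` enumerates every assignment of
observed patterns to residues (symmetry-reduced over identical
residues), every substitution-pattern choice for unobserved uronic
residues (subsets of the allowed positions, capped at two sites), and
every tree over the resulting typed residues: each substituted position
is a slot, each residue donates its anomeric bond into exactly one slot
(in repeat mode one slot receives the exit bond), and assignments that
fail to form a tree rooted at the chosen residue are discarded.
Identical-class residues are interchangeable, so candidates are
generated unlabeled and deduplicated canonically.

Two structural equivalences matter:

* **Isomorphism** — residue-id relabeling.  The canonical form orders
  children by (parent position, canonical substring) and is the dedup
  key everywhere.
* **Phase rotation** — a repeat unit can be rooted at any residue of its
  backbone cycle; all rotations generate the same infinite polymer and
  no observation in this evidence model can separate them.  Repeat-mode
  candidates are therefore deduplicated by the *polymer* canonical form
  (minimum canonical string over rotations), and recovery of a known
  structure is judged up to rotation (`same_polymer`).

`prune` applies the observation constraints as a conjunction, cheapest
first (adjacency and HMBC edge checks, then fragments ordered by size);
the run report tallies candidates before/after each constraint, and an
empty result names the first constraint that eliminated the last
candidate.  There is no scoring or ranking: an ambiguous evidence set
yields the full candidate list, flagged as such.

Because the constraints are a conjunction, `StructureElucidator` by
default also applies the linkage evidence (HMBC bonds and adjacencies)
*during* candidate generation: position choices for PMAA-invisible
uronic residues that cannot host the required bonds are skipped before
tree enumeration, and generated trees failing an edge check are dropped
before canonicalization.  This changes nothing about which structures
survive (asserted by a test) but keeps worst-case search spaces —
several uronic residues with unobserved patterns — at seconds instead
of minutes.  `screen_with_edges=False` restores the fully staged run
whose report shows each constraint's eliminations.

Search-space defaults: at most 8 residues, at most 2 substituted
positions per residue, parent positions {2,3,4,6}.  All are arguments of
`StructureElucidator`.

## Fragment enumeration

Fragments of size *k* are enumerated as rooted connected subtrees over a
finite chain of `ceil(k / L) + 2` unit copies, where *L* is the backbone
cycle length (the number of residues on the attachment→root path).  The
backbone length — not the unit size — bounds how many copies a fragment
can traverse: a unit whose residues mostly sit on side chains has a
short backbone, and a k-residue fragment can snake through up to
`ceil(k/L)` periods of it.  (The property test that compares against a
naive connected-subset oracle caught exactly this case.)  Enumerating
over one extra copy leaves the canonical fragment set unchanged, which
is asserted as a test invariant.

## Mass arithmetic

Masses are element-count formulas evaluated with IUPAC monoisotopic
atomic masses (hard-coded to 6 decimals); average masses serve only the
repeat-unit molar mass used by the rotation module.  Anhydro residues
are Hex C6H10O5, dHex C6H10O4, HexA C6H8O6; a free reducing end adds
H2O.  Ionization adds a proton *mass* (1.007276 Da — an H atom minus an
electron); +Na/+K/+NH4 adducts likewise subtract the electron mass, and
this convention reproduces the reference derivative ion at 658.2931 to
the printed precision.  Permethylation methylates free hydroxyls, the
anomeric hydroxyl (two alditol hydroxyls after borohydride reduction)
and uronic carboxyls; CD3 permethylation differs by 3.018831 Da per
methyl.  The y ion at a glycosidic cleavage keeps the glycosidic oxygen
plus a proton (and stays unmethylated at that position); the b ion is
the bare anhydro piece, so b + y equals the parent neutral mass exactly.
The 1,5X (y′) ion is y + 27.994915 Da (+CO), the retained C-1/O-5 ring
remnant under a homolytic atom partition; published spectra rarely state
the convention, so the delta is a documented, configurable constant and
no test oracle depends on it.  Default m/z matching tolerance is 0.01 Da,
configurable per call.

Two printed masses from the reference study are deliberately *not*
modelled: the 1008.39 Da extracted-ion mass of the five/six-residue
fragment window (not unambiguously assignable to an adduct/reduction
state) and the 503.3 MALDI fragment (no stated ion type or
methyl-isotope assignment).  Both are treated as exploratory.

## Optical rotation

Molar rotation is purely additive over residue contributions keyed by
(name, anomeric, D/L), per Hudson's isorotation rules in the methyl
glycoside convention.  Specific rotation is `100 × [M]_D / M` with `M`
the *average* mass of one anhydro repeat (no terminal water): with the
hexasaccharide's M ≈ 970.8 g/mol this convention — and no other water
bookkeeping — converts the two published molar-rotation sums into the
published +126/+87 pair, which is the criterion the module is tested
against.  The shipped constants table uses classical Bates/Hudson methyl
glycoside values for the neutral hexoses; the galacturonic-acid and
6-deoxy-talose entries are back-calculated from the published additive
sums (the primary literature values are not reproduced in the source
text), each entry carries its provenance note, and users can override
the whole table via YAML.  `assign_configuration` picks the candidate
minimizing |measured − predicted| and reports a margin; ties within the
reported precision (default 0.5°) return "indeterminate" rather than a
guess.

## NMR utilities

No spectral processing: inputs are assigned shift tables and correlation
lists.  Anomeric-signal counting rounds shifts to 2 decimals and counts
coinciding resonances once, recording multiplicity — reproducing the
"signal of double intensity" reading of overlapping anomeric carbons.
The packaged table stores the interchangeable-assignment footnotes as
per-cell ambiguity flags; no algorithm consumes the flagged cells.  The
window of a counting query is always an explicit argument, since the
source table itself does not define the spectral regions.
`check_structure_vs_hmbc` reports confirmed, uncovered and contradicted
bonds; "consistent" means no contradictions — uncovered bonds are
expected (the reference case leaves the GalA→Gal backbone bond and the
exit bond to be established by fragment evidence and elimination).

## Synthetic world

`random_repeat_unit` samples 3–8 residues (uniform) from a weighted
alphabet dominated by Glc/Gal with occasional Man, 6-deoxy sugars and
uronic acids (realistic for acidic heteropolysaccharide repeats, and
roughly matching the reference unit's 4:1:1 neutral/acidic/deoxy make-up);
trees grow by uniform attachment with a 0.2 branch probability and at
most two substituents per residue, exit placement included — keeping the
generated world inside the solver's default search space.
`simulate_observations` projects a unit onto the evidence channels:
exact composition, PMAA with uronics masked, one fragment observation
per distinct (composition, reducing-end) signature at sizes 3…n, an
adjacency per HexA bond, and HMBC edges (with substitution refinements)
at 0.8 coverage.  Noise is omission only — fragment dropout 0.3,
independent per signature — because the real channels are presence
calls, not noisy intensities.  One integer seed drives separate
numpy substreams per channel, so fixtures are exactly reproducible and
raising dropout on a fixed seed removes observations monotonically.

What a green synthetic test does establish: soundness (the true polymer
is never eliminated by observations simulated from it) and, with full
information, near-complete identifiability for small units.  What it
does not establish: robustness to *corrupted* observations (wrong
reducing-end calls, misassigned HMBC), detector-response effects, or
acid-lability bias in fragment yields — none of which are modelled.

## Known limitations

* Same-mass, same-class residues (Glc vs Gal vs Man) are
  distinguishable only where observations name them; class-level
  observations leave genuine ambiguity sets, which are returned whole.
* PMAA compatibility resolves the "(or 5-substituted furanose)" reading
  of deoxyhexose patterns to 4-substituted pyranose, since the absence
  of furanose signals is part of the reference evidence.
* The exhaustive candidate space grows steeply with residue count and
  pattern multiplicity; size-8 units with several identical patterns
  take tens of seconds.  The 8-residue default cap is a practical
  boundary, not an algorithmic one.
* Polymer-phase equivalence means a reported unit may be written in a
  different rotation than a publication's chosen phase; `same_polymer`
  and `rotations()` make the equivalence explicit.
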