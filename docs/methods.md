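# Methods

## Scope and model

`protonwire` treats proton translocation purely geometrically: a
candidate proton wire is a chain of hydrogen-bonded donors, acceptors
and waters connecting the buried active-site metal to the solvent. No
energetics, kinetics or conformational sampling are computed; the claim
the pipeline can support is "this chain of tight hydrogen bonds exists
in the crystal geometry after plausible protonation", not "protons flow
along it at a given rate". Proton flow direction is not modelled —
paths are undirected chains, as the underlying enzymes are
bidirectional.

## Structure model

PDB ATOM/HETATM records are read into a typed Atom/Residue/Structure
hierarchy. Author residue numbering is kept verbatim. Waters (HOH/WAT)
form a separate pool; hetero groups NI, FE, SF4, F3S are classified as
metal sites (other non-CHNOS hetero groups are kept but only flagged
`other`, and never drive protonation rules). For alternate locations
the highest-occupancy conformer is kept, ties going to the
alphabetically first alt-loc — a deterministic single-conformer policy
matching single-model analysis. Only MODEL 1 of multi-model files is
read. Atomic masses come from gemmi's periodic table; atoms with
unrecognisable elements get mass 0 and are excluded from centres of
mass with a warning.

The centre of mass (COM) of a residue is Σmᵢxᵢ/Σmᵢ. By default only
heavy atoms enter — crystallographic models carry no hydrogens, and
adding constructed hydrogens moves an amino-acid COM by well under
0.1 Å. Both conventions are exposed because tabulated metal-to-COM
distances in the literature rarely state which was used.

## Protonation microstates

Published protonation engines select states by minimising a free-energy
function over discrete microstates. This package instead applies an
explicit, reproducible rule set, documented as an approximation and
sufficient for the qualitative assignments the pathway analysis needs:

- **Fixed metal-site constraints** (never re-titrated): [4Fe4S] irons
  +2/+2/+3/+3, [3Fe4S] irons +3/+3/+2, cluster/active-site cysteines
  −1 (thiolate, no S–H), inorganic sulfides −2, active-site Ni and Fe
  +2. Cysteines are recognised as ligating when SG is within 2.6 Å of
  a metal atom (a standard coordination distance).
- **pH 7.4 defaults**: Asp/Glu anionic, Lys/Arg cationic, Cys neutral.
- **Metal-proximity neutralisation**: a cationic side chain whose
  charged-group heavy atoms lie within 5.0 Å of a fixed metal cation is
  assigned its neutral form. A buried positive charge with no
  compensating anion next to Ni²⁺ is electrostatically untenable; the
  5.0 Å default covers the ~4.8 Å Ni–guanidinium separation seen in
  the hydrogenase active site while leaving ordinary surface residues
  untouched. For a neutral arginine the η-hydrogen with the poorest
  hydrogen-bond prospects is the one removed.
- **Histidine tautomers** maximise the number of satisfiable
  ring-nitrogen interactions, evaluated on heavy-atom geometry
  (acceptors = oxygens and ligating thiolates within 3.5 Å; donors =
  groups that will carry hydrogens under the default rules). A
  histidine becomes HIP (+1) only when *both* ring nitrogens see an
  acceptor in range and at least one partner is an anionic oxygen —
  the situation where a doubly protonated, positively charged
  imidazole is stabilised. A ring nitrogen within 2.6 Å of a metal is
  forced bare (metal ligation). Ties between HID and HIE go to HIE,
  the more common tautomer. Other histidines' ring nitrogens are not
  counted as acceptors during assignment, keeping the rule order-free.

Terminal amide (Asn/Gln) and histidine ring flips are deliberately not
performed; heavy atoms are trusted as deposited. This is a known
limitation (a mis-built amide can hide a hydrogen bond) accepted for
determinism, and flagged as the natural extension point.

## Hydrogen construction

Only polar hydrogens are built — carbon-bound hydrogens play no role in
hydrogen-bond donation. Bond lengths are the conventional ideal values
(N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å); heavy atoms never move. Planar
sites (backbone amides, ring N–H along the external bisector in the
ring plane, amide NH₂, guanidinium) are constructed analytically.
Rotatable donors (Ser/Thr/Tyr hydroxyls, Cys S–H, Lys ammonium,
N-terminal amines) are swept on a 5° grid about their rotor axis and
set to the phase that satisfies the most acceptors, ties broken by the
smallest summed H···A distance, then by the lowest grid index — fully
deterministic. Waters are built with a seed-derived initial orientation
(seed and residue number feed the RNG, so orientation is independent of
iteration order), then optimised.

Water orientation is a greedy iterative sweep (default 5 passes, in
residue order): each water is re-oriented to maximise the hydrogen
bonds it donates, ties again by summed H···A distance, stopping when a
full pass changes nothing. Candidate orientations point one hydrogen
exactly at an acceptor and tilt the second toward another; a water
midway between two acceptors subtending the H–O–H angle recovers both
contacts exactly. Isolated waters keep their seeded orientation.

## Hydrogen-bond criterion

A donor–H···acceptor triple is accepted when d(D···A) ≤ 3.5 Å and the
angle between the vectors D→A and H→A is below 30°. Note this is the
literal criterion implemented — the angle at the *acceptor side*
between those two vectors, not the more common D–H···A angle. Donors
are N/O/S atoms carrying at least one hydrogen; acceptors are all
oxygens, bare histidine ring nitrogens and cysteine thiolates. Atom
pairs within three covalent bonds are excluded (the bond graph is
inferred from standard covalent distance ranges), which removes
intra-group contacts and the amide-to-preceding-carbonyl artefact.

Bonds with d(H···A) ≤ 2.2 Å are classed **strong**. Tight,
proton-relay-grade contacts in high-resolution structures run
~1.5–2.0 Å, ordinary hydrogen bonds ~2.4–2.6 Å; 2.2 Å separates the
two populations conservatively and is configurable.

## Graph and pathway search

Nodes are polar groups: one per side-chain functional group, one per
backbone amide and one per backbone carbonyl per residue, one per
water, one per metal atom. Distinct groups of one residue are distinct
nodes, so a pathway cannot short-circuit through a residue's covalent
skeleton. One undirected edge per node pair carries the geometrically
best (smallest H···A) bond between them; bifurcated bonds are all kept
at detection level and collapse to the best at graph level.

Metals join the graph via zero-length edges: coordination edges to
side chains within 2.6 Å at build time, and source-attachment edges to
side chains within 5.0 Å at query time (the active-site pocket's
second shell, covering the ~4.8 Å metal–arginine relation). Both
cutoffs are configurable and distinct on purpose.

Pathways are simple paths from the source to sink nodes, enumerated
exhaustively up to 12 nodes — head-room above the ~10-node chains such
wires exhibit — and ranked by (bottleneck, total length, node count,
lexicographic node ids). The bottleneck (minimax) criterion encodes
that a proton wire is limited by its weakest hop. The top path's
bottleneck is checked against an independent brute-force minimax
enumeration in the tests. Ranking is insensitive to node insertion
order; a missing connection yields an empty list, not an error.

Sinks are either explicit residues or, automatically, surface-exposed
polar residues. Exposure offers two methods: Shrake–Rupley accessible
surface (probe 1.4 Å, 256 deterministic sphere points per atom via
biotite, waters excluded as occluders) relative to per-residue
theoretical maxima, exposed at ≥ 0.2 relative accessibility; or a
neighbour-count heuristic — exposed when fewer than 18 heavy atoms of
other residues lie within 8 Å of the side-chain tip atom. The SASA
threshold 0.2 is the conventional buried/exposed boundary; the
neighbour-count variant is cheap and robust on sparse synthetic scenes.

## Conservation

Pairwise percentages categorise alignment columns as identical,
strongly similar or weakly similar using the Clustal residue groups
(strong: STA NEQK NHQK NDEQ QHRK MILV MILF HY FYW; weak: CSA ATV SAG
STNK STPA SGND SNDEQK NDEQHK NEQHRK FVLIM HFY). The default
denominator is the alignment length excluding all-gap columns;
`shorter` (length of the shorter sequence) is available since published
percentages rarely state their convention. The built-in pairwise
aligner uses Gonnet scores with affine gaps (open −10, extend −0.2,
end gaps free); a precomputed-alignment entry point accepts external
aligner output when bit-compatibility with a specific tool matters.

Motifs use PROSITE-like patterns (`H-x-H-x(2)-H-x(2)-H-x-H`, compact
`HxHxxHxxHxH`, or `Hx6L`); matches are reported 1-based in ungapped
coordinates, overlapping matches included, and the scanner is checked
against a brute-force sliding window. Alignment columns are mapped
onto chain residues through the reference row (requiring ≥ 95%
identity, flagging residual mismatches), and pathway residues are then
annotated with per-column identity and Clustal category; waters become
"structural water".

## Synthetic data

The wire generator plants a chain of alternating serine hydroxyls and
waters with exact O···O spacing (default 2.8 Å, jitter optional). The
chain zig-zags with a turn angle equal to the water H–O–H angle
(104.5°), so an optimally oriented water donates one hydrogen to each
neighbour — the geometry of an ideal relay and the reason recovery at
zero noise is exact by construction. The pseudo-metal sits 3 Å from
the first node; decoy waters are placed at a minimum separation from
the wire (default 4 Å, outside hydrogen-bond range); an optional
carbon shell of 7 Å radius buries the source end while a channel along
the wire stays open. Serine backbones point out of the wire plane at
distances that cannot form spurious bonds to the wire at the default
spacing.

What the generator does **not** emulate: real protein packing density,
backbone-mediated hydrogen-bond networks, bifurcated-bond ambiguity,
alternate conformations, or crystallographic noise in heavy-atom
positions. Passing the planted-wire suite therefore demonstrates the
correctness of the machinery (protonation → detection → graph →
ranking) on controlled geometry, not performance on real structures —
that is what the real-structure checks against published reference
values are for (they need the user-supplied files described in
`data/README.md`, since those inputs are not redistributable here).

The alignment generator mutates rows independently from a common
ancestor at a stated per-column rate, keeping motif columns invariant,
and returns the planted start positions as ground truth.

## Numerical and reproducibility choices

- Rotor grid 5°; water candidate orientations are finite and
  seed-deterministic; all ties break lexicographically or by residue
  order. Identical inputs and seed give bit-identical hydrogens,
  reports and serialized output (verified byte-for-byte in the tests).
- Distances are exact float64 geometry; rigid-motion invariance of
  COMs and pairwise distances holds to 1e-9 Å in the tests.
- Degenerate inputs: residues missing the heavy atoms a variant needs
  get a warning and no hydrogens; waters without oxygen are skipped;
  an empty hydrogen-bond list still yields a graph with nodes; a
  search with no route returns an empty list.
- Problem sizes: the self-contained suite uses 6–8-node wires (tens of
  atoms), 100 recovery seeds, random ranking graphs up to 12 nodes and
  20-row alignments of length 120–400; the acceptance script mirrors
  those sizes. A full crystal structure (~4,500 heavy atoms, ~700
  waters) runs through the whole pipeline in well under five minutes
  on one CPU, dominated by water orientation and path enumeration.

## Known limitations

- Protonation is rule-based, not thermodynamic: no pKa shifts from the
  local field, no coupled titration, no amide/ring flips.
- The hydrogen-bond model ignores C–H donors, π-acceptors and any
  energy weighting; the literal acceptor-side angle criterion is kept
  for fidelity even though D–H···A is more common.
- SASA reference maxima are tripeptide-based theoretical values;
  relative accessibility above 1 is possible for very exposed residues.
- Pathway enumeration is exhaustive over simple paths and can grow
  combinatorially on dense graphs; the strong-bond restriction and the
  12-node cap keep it tractable on real structures.
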