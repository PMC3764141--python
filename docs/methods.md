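# Methods

## Scope and model

The package annotates tertiary interactions in RNA 3D structures by
explicit geometric criteria, rather than by subgraph matching against a
motif library or by manual inspection. Its unit of analysis is the
nucleotide with author numbering — every motif is reported by the
`chain:BaseNumber` identities a structural biologist would cite — and its
core primitive is the hydrogen bond inferred from heavy atoms only
(crystallographic RNA structures rarely include hydrogens).

### Hydrogen bonds

A donor-acceptor contact is accepted when the heavy-atom distance lies in
[2.2, 3.5] Å and the angle at the donor, measured through each covalent
antecedent of the donor atom (e.g. C6 for adenine N6; both C2 and C6 for
guanine N1), is at least 110°. The antecedent construction stands in for
the unresolved hydrogen: a bond roughly opposite the antecedents is one a
real N-H/O-H could make. Donor and acceptor tables cover the base edges,
the 2'-hydroxyl (donor and acceptor) and the phosphate oxygens, and each
bond is tagged by moiety (base / sugar / phosphate) because the motif
definitions discriminate on it. The 3.5 Å / 110° values are conventional
crystallographic choices; the source survey names no numeric criterion,
so both are exposed in `DetectionConfig`.

### Base pairs

A pair needs at least two **base-base** bonds (sugar-mediated bonds do
not count by default; `count_sugar_bonds_in_pairing` switches this) and
base planes within 65°. The loose planarity is deliberate: propeller
and buckle in real pairs are large, and "planar" is enforced strictly
only at the triple stage. Edges follow the standard three-edge
nomenclature; each bonded atom votes for the edge(s) it belongs to
(atoms shared between edges, like guanine O6, carry half a vote each)
and the majority assigns the edge. Orientation is cis when the two
glycosidic C1'→N vectors fall on the same side of the pairing axis.
Watson-Crick canonicity for census purposes means cis WC/WC G-C or A-U
only; the G-U wobble is flagged separately and is never counted as a
"Watson-Crick pair" in triple statistics.

### Base-plane frames

The frame of a base is the least-squares plane of its ring atoms
(purine: N9 C8 N7 C5 C6 N1 C2 N3 C4; pyrimidine: N1-C6), with the normal
signed by base chirality (cross product of two ring-bond vectors) so
that frames are rigid-transform equivariant and sequential residues of a
strand share a hemisphere. Nucleotides with fewer than five ring atoms
get no frame and are excluded from planarity-dependent detectors.

### Triples, quadruples

A triple is a residue paired (by the accepted pair list) to two others,
with all three base planes mutually within 30°. The 30° cutoff
operationalizes "planar": trial geometry shows stacked contacts sit near
90° while in-plane triples sit well below 30°. Triples are counted per
unordered residue set; two triples sharing a pairing merge into a
quadruple record, but the constituent triples remain in the census (the
count statistics are defined over triples). Composition labels are
written purines-first (A < G < C < U), so the common adenosine-docked
G-C pair triple reads "AGC".

### A-minor / G-minor

A docking residue (A or G) must place its sugar-edge atoms (N3, O2') in
the minor groove of a canonical receptor pair — operationally, at least
two hydrogen bonds from {N3, C2, O2'} of the dock to the minor-groove
atoms of the receptor (purine N3/N2, pyrimidine O2, either O2'), with
the dock not itself WC-paired to the receptor. Typing is an operational
restatement of the standard taxonomy: only-O2' contacts → type 0; N3 and
O2' both engaged with both receptor residues touched → type I; contacts
confined to one receptor residue → type II. Type III (no minor-groove
insertion) is not emitted. When one residue bonds several canonical
pairs, the best-supported receptor (most bonds, then shortest) wins and
one record per docking residue is emitted. The receptor label is written
5'-residue first; because the convention behind published GC-vs-CG
splits is not fixed, the flipped label is always carried alongside and
the convention is a config switch.

### Ribose zippers

Two dinucleotide segments (author-consecutive residues), at least 4
apart in sequence or on different chains, joined by ≥ 2 cross-segment
bonds each involving an O2'. Classes by bond signature: canonical =
O2'-O2' plus O2'-base(O2/N3); pseudo-cis = O2'-base bonds without an
O2'-O2'; anything else = other-variant. Overlapping candidate windows
are resolved most-bonds-first.

### Pseudoknots, kissing loops

The nested skeleton is the maximum-cardinality non-crossing,
one-pairing-per-residue subset of canonical+wobble pairs, computed by
interval dynamic programming with ties broken toward more hydrogen
bonds, then lexicographically. Canonical pairs left outside the skeleton
that cross it are merged (mutually nested pairs crossing common skeleton
pairs) into pseudoknot records; a record is H-type when its residues
reach into a hairpin loop. Kissing loops are ≥ 2 canonical pairs joining
two distinct hairpin loops — they will typically also appear as a
crossing-pair record, and the census de-duplication (below) keeps the
more specific kissing-loop class.

### Kink-turns, loop-receptors

A kink-turn is matched as: tandem sheared G·A pairs (Sugar/Hoogsteen
edges, adjacent on both strands), a 2-4 nt bulge separating them from a
canonical stem, and stem axes (principal component of C1' positions)
within 120°; an internal A-minor from the NC side into the C-stem is
attached when present. A loop-receptor is a hairpin loop of 4-5
residues whose members contribute ≥ 1 A-minor into a distal stem, with a
ribose zipper attached when one zipper strand lies in the loop. The
loop size distinguishes the tetraloop from the pentaloop variant.

### Secondary-structure labels and contexts

Stems are maximal stacked runs of skeleton pairs, numbered P1..Pn in
5'-order; runs separated only by internal loops/bulges share a number
with letter suffixes (P2a/P2b). Hairpin loops take their stem's number
(L2 closes P2); unpaired runs between stems are junctions "Ji-j". Motif
contexts are rendered from the multiset of element kinds touched
("Helix - junction interaction (P2b & J3-4)", "Bulged-out residue -
helix interaction (P1)", ...), matching the published context strings
where the underlying topology matches; where automatic lettering
diverges from historical riboswitch nomenclature, a label mapping can be
applied downstream.

### Conservation

Columns are profiled over all rows; a column is conserved when its modal
base frequency strictly exceeds 0.95. Gaps count in the denominator by
default (a half-gapped column can never be conserved); the non-gap
denominator is a config switch since published rules rarely state this.
Structure sequences enter the alignment by pairwise insertion: the query
is globally aligned (match +2, mismatch −1, open −5, extend −1) against
the row with highest identity, inherits that row's gap pattern, and any
surplus residues open new columns flagged as inserts and excluded from
conservation reporting. This replaces covariance-model alignment — the
one deliberate methodological substitution in the package — and is why
absolute conserved-position totals from specific alignment releases are
not reproduced here; per-motif conservation *classes* (fully conserved =
every column at 1.0 with the structure's own base modal; highly
conserved = every column > 0.95; else variable) are the supported
output.

### Superposition

Correspondences come from global sequence alignment; each matched
residue contributes P (optional at 5' termini), C4', C1' and the
glycosidic nitrogen. The fit is the closed-form least-squares rotation
(SVD with the reflection excluded). Pruning, when enabled, discards the
single worst pair above the 2 Å cutoff and refits until stable —
worst-first because a gross outlier skews the initial fit enough to push
good pairs past the cutoff.

## Synthetic scenes: what they are and are not

The generator builds scenes from idealized planar base templates
(standard-reference-frame ring coordinates) carrying five-atom
sugar/phosphate stubs (C1', C2', O2', C4', P). Fragments are placed by
constrained rigid fitting: named donor-acceptor distances are driven to
~2.9 Å while steric clashes are avoided and the donor's antecedents are
held back far enough to guarantee the 110° bond angle. Helices stack
pairs at 32.7°/2.81 Å per step. The stub O2' is positioned so that the
N3···O2' span (~4.2 Å) and its direction match an anti nucleoside well
enough for sugar-mediated motifs to be geometrically realizable; there
is no backbone continuity, no energy model, and loop residues are simply
scattered out of bonding range. Consequently, passing closure tests
shows the detectors implement their stated criteria exactly — it does
not show robustness to thermal noise, modelling error, modified
residues, or the crowded contact environment of a full-size aptamer,
which only the census over deposited structures exercises. The scenes
are written as PDB files and re-read, so the parser is part of every
tested path.

The alignment generator plants an exact modal count per column
(round-half-up of fraction × rows) and distributes the remaining rows
evenly over the other bases, refusing fractions that would leave the
modal base ambiguous; the plant, after rounding, is the oracle for the
conservation tests.

## Problem sizes and numerical choices

Test scenes are 3-26 residues; brute-force oracles (all-pairs hydrogen
bond scan, all-triples enumeration, 2^n non-crossing subset search) run
on ≤ 20 residues / ≤ 12 pairs, where exhaustive enumeration is exact and
fast. The constrained placement uses multi-start Levenberg-Marquardt
over rigid transforms, seeded constructively (bonded atoms swept over
their constraint spheres, plus the spin about the bond axis); the fit is
accepted only with every bond within 0.1 Å, no clash below 2.4 Å and
donor-angle proxies satisfied, and placements are cached per pair
geometry. Ties in the skeleton DP, stem naming, motif ordering and
report writing are all resolved deterministically, so identical inputs
give byte-identical reports.

## Known limitations

* Pair classification uses one edge per base; bifurcated pairs that
  genuinely straddle two edges are assigned their majority edge.
* The orientation rule (projected glycosidic vectors) is a robust
  approximation; near-perpendicular pairs close to the cis/trans
  boundary may be labelled either way.
* A-minor typing is an operational restatement; structures annotated by
  visual inspection in the literature can disagree near type
  boundaries.
* T-loops and stacked tetrads are not auto-detected (historically found
  by eye); they can be asserted via residue lists in configuration.
* Sub-stem lettering follows deterministic 5'-order, which may diverge
  from historical labels (P2a/P2b) in some families; contexts are then
  consistent internally but need a label map for literature comparison.
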