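# Methods

This note documents the models, conventions and parameter choices behind
`bivalens`, in the order the pipeline applies them, together with what the
synthetic generator does and does not emulate.

## Structures, selections and PDB handling

Atom records carry PDB author numbering (1-based residue numbers,
insertion codes part of residue identity), coordinates in Å, and an
optional van der Waals radius.  Parsing and serialisation go through
biotite; on top of that the package enforces the invariants the pipeline
needs: multi-model files are read model by model and verified to share an
identical (chain, residue, insertion code, atom name) sequence — biotite
alone takes annotations from the first model and would not notice a
permuted atom order — and malformed coordinate fields are reported with
their line number from a pre-scan.  Alternate locations are resolved per
atom to the highest occupancy, ties going to the first record encountered.
HETATM records and waters are excluded on read by default.  Selections are
declarative (chains, inclusive residue ranges, atom names) with
intersection semantics; a selection that matches nothing raises rather
than silently producing an empty set, because empty selections would
corrupt RMSD and SASA results downstream.  This is also how stalk
exclusion is expressed: the membrane-proximal stalk is simply left out of
the residue range used for RMSD.

Van der Waals radii default to a standard single-atom set (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, H 1.20 Å) and can be replaced by a two-column text
table.  Hydrogens are retained in structures but a heavy-atom mask is used
for centroids and contact checks; crystal structures lack hydrogens while
MD snapshots have them, so analyses that must be comparable across both
default to heavy atoms.

## Superposition and RMSD

Rigid superposition is the Kabsch algorithm: SVD of the coordinate
cross-covariance with the sign of the smallest singular vector flipped
whenever the raw solution would be a reflection, so every returned
rotation is proper (det +1).  Collinear point sets (rank < 2 after
centering) are rejected as degenerate because the rotation about the line
is undetermined.  `rmsd_after_fit` fits and reports on the same declared
selection; ensemble series are measured against frame 0 of each
trajectory (the initial conformation), not a running average.  The atom
set for receptor alignment defaults to the full declared fit selection;
for protein work a Cα-only selection is the intended default and is
expressed through the selection itself (`atoms=CA`).

Tests validate the implementation against two independent routes: scipy's
`Rotation.align_vectors` and a brute-force numerical minimisation of RMSD
over rotation vectors.

## Template docking

The binding-mode template is a single PDB complex (receptor monomer +
ligand) with three declared selections: receptor-fit atoms, ligand atoms
and the ligand's carboxy-terminal-domain atoms (a subset of the ligand,
used for clash scoring).  Docking superposes the template's receptor-fit
atoms onto the identity-matched atoms of a frame monomer — pairing is by
(residue number, insertion code, atom name), deliberately ignoring chain
id so a template chain R can dock onto frame chains A and B — and applies
the fitted transform to the ligand.  Docking is equivariant under rigid
motions of the frame and never moves receptor atoms.  The fit RMSD is
recorded per dock; values above a ceiling (default 3.0 Å, an engineering
choice flagging distorted monomers) raise a warning and mark the frame's
record, but do not abort, since a distorted fit may still be informative.

## Surface areas

SASA is Shrake–Rupley: each atom's accessible sphere (radius
`r_vdw + probe`) is sampled with a deterministic golden-section-spiral
point set and the exposed fraction scales the sphere area.  Defaults:
probe 1.4 Å (water), 960 points per atom — at 960 points the isolated
sphere is exact by construction and irregular bodies are within a
fraction of a percent of a 10⁵-point brute-force integration; 4000 points
are used where extra precision is wanted.  The point set is fixed in
space, so results are deterministic but rotating a body changes totals by
discretisation-level amounts (≪ 1 %); the classifier is insensitive to
this because it tests zero versus tens of Å².

Buried surface between two disjoint groups is the per-side convention
`(SASA_A + SASA_B − SASA_complex)/2`.  The implementation subtracts
per-atom areas pairwise before summing, so two groups with no cross-group
pair inside occlusion range (`r_i + r_j + 2·probe`) give exactly 0.0, not
a small float — the zero-vs-nonzero distinction is the entire valency
readout, so it must be exact.  Negative round-off is clamped to zero.

## Valency classification

A frame is bivalent-competent iff the buried area between the two docked
ligands' scoring selections is ≤ the zero tolerance.  The tolerance
(default 1.0 Å², inclusive at the boundary) absorbs discretisation noise;
it is reported in every output.  Scoring defaults to the ligands'
carboxy-terminal domains — the membrane-proximal domains where the steric
clash occurs — with a whole-ligand mode available; for geometries where
the clash is C-terminal the two modes agree on the flag, and the whole-
ligand area is by construction at least the domain-restricted one.
Frames are sampled with a configurable stride (default 1).  Per-trajectory
fractions are combined by an unweighted arithmetic mean (each trajectory
counts equally, regardless of length); the frame-pooled weighted mean is
also computed and reported alongside.

## Dimer geometry and constructed conformations

The descriptor of a dimer frame reports: binding-site separation and
interface gap (distances between heavy-atom centroids of the respective
selections), opening angle (angle between the subunits' first principal
axes, each axis oriented from the interface-anchor centroid toward the
binding-site centroid so the sign convention is deterministic), and twist
(angle between the axes' projections onto the plane perpendicular to the
monomer-centroid connection line).

`reorient_dimer` rotates one whole chain rigidly about the interface axis
— the line through the two interface-anchor centroids — or a custom axis.
The build is accepted only if every residue of a declared
interface-preservation selection retains at least one heavy-atom contact
within a cutoff (default 5.0 Å) of the partner subunit; otherwise the
build is rejected and the lost contacts are named.  This encodes the
constraint that a reoriented dimer must keep the original hydrophobic
interface residues in the interface.  The rotation angle is a free
parameter; the package documents behaviour across a sweep rather than
privileging a single value.

`graft_onto_dimer_template` pairs a monomer with each subunit of a target
dimer by residue/atom identity, superposes, and emits two rigid copies in
the target's arrangement — the construction used to start a compact
receptor from an open homologue's dimer orientation.  All constructions
are exactly rigid per subunit (internal distances preserved to machine
precision).

## Synthetic toy systems and what they do (not) show

The generator emulates the geometry that decides valency and nothing
else.  The monomer is an elongated cluster on deterministic lattices:
a 6-atom interface-anchor ring at the base (residues 1–6), a body of
stacked ≥3-membered rings, and a 6-atom binding-site ring at the tip —
every ring is rotation-symmetric about the monomer axis, which makes the
principal axis exactly the geometric axis and the opening-angle
descriptor exact for constructed frames.  The ligand is two exactly
centrosymmetric Fibonacci shells (radius 3 Å, 12 atoms each) on the
monomer axis: a distal binding domain 6 Å beyond the tip and a proximal
carboxy-terminal domain a further 19 Å out.  Defaults: monomer length
20 Å, 24 atoms, interface offset 2 Å, all atoms carbon (r = 1.70 Å).

A dimer frame places two copies about a C2 axis with a given opening
angle and twist, plus optional i.i.d. Gaussian coordinate jitter (default
0.05 Å).  Because the ligand is coaxial and the shells are
centrosymmetric, the separation of the two docked C-terminal-domain
centroids has the exact closed form

    s(α) = interface_offset + 2 · d · sin(α/2),   d = 45 Å,

and the hard contact bound below which buried surface can be nonzero is
`2·(shell radius) + 2·(r_vdw + probe)` = 12.2 Å.  Ground-truth flags
compare `s(α)` with this bound.  When a bivalent fraction is programmed,
frames are drawn from two well-separated regimes — compact 2.5° ± 1°
(clipped to [0°, 5°], giving s ≤ 6 Å: deep interpenetration, buried areas
of order 100 Å²) and open 50° ± 5° (clipped to [35°, 65°], s ≥ 29 Å, far
beyond the bound) — in exactly the programmed proportion (rounded to the
nearest frame count, shuffled by seed), so classifier agreement must be
exact.  A continuum mode samples a single Gaussian over angles for
monotonicity studies; there the truth flag follows the closed form and
per-frame margins are reported so frames near the boundary can be
identified.  All randomness comes from numpy's PCG64 generator seeded by
the caller; outputs are bit-reproducible from the seed.

What passing these tests shows: the docking, surface and aggregation
machinery is geometrically correct, deterministic, and recovers known
valency fractions exactly under unambiguous geometry.  What it does not
show: anything about force fields, solvation, side-chain packing,
conformational kinetics, or the actual fractions a particular receptor's
MD ensemble would produce — toy bodies are rigid lattices, not proteins,
and the generator's angle regimes are stipulated, not simulated.

## Numerical choices and limitations

- Degenerate inputs: coincident atoms warn but areas remain defined;
  empty selections, collinear fits, partial-chain moves and topology
  mismatches raise typed errors.
- Determinism: fixed sphere point set, seeded generators, sorted JSON
  keys and fixed float formatting make repeated runs byte-identical;
  timings go to stderr only.
- Problem sizes in the shipped analyses (200-frame ensembles, 960 sphere
  points, 10⁵-point oracle integrations) were chosen to characterise the
  method precisely at interactive cost on one CPU.
- The per-side ½ factor in buried surface is a convention; the classifier
  is insensitive to it because it tests zero versus nonzero.
- Statistical error bars on fractions (beyond the across-trajectory
  spread) and clustering of conformers are out of scope.
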