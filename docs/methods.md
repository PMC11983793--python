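# Methods

This note documents the models, conventions and numerical choices behind
`phenolig`, and what the synthetic fixtures do and do not demonstrate.

## Structures and entities

Input is PDB (wwPDB v3.3 columns); trajectories are multi-model PDB files
sharing one topology — binary trajectory formats are out of scope, and
conversion is left to the user. Alternate locations default to the
highest-occupancy conformer, ties resolved to the lexicographically first
altloc label. Insertion codes are part of residue identity. Entity classes
are assigned per residue: HOH/WAT/TIP-style names are water; single-atom
residues named after a metal (NA, MG, ZN, FE, MN, NI, CA, CU, K, ...) are
metal ions; the twenty standard amino acids are protein; user-listed
component identifiers are cofactors; all remaining HETATM residues are
ligands. Unknowns fall to "other" and are logged rather than raised.

All distances are Euclidean in Å and all cutoffs are inclusive (≤). A
binding site is every non-ligand atom within 7.5 Å of any ligand atom —
waters and ions included — matching the cutoff used for the pair counts.

## Ligand screening and classification

Screening uses linear-path fingerprints: every bond path of length 1–7
hashed onto 1024 bits (RDKit's path fingerprint). The exact bit layout is
toolkit-specific, so absolute similarity values transfer only within this
package; the screening decision depends on the Tanimoto threshold alone,
which is the property the tests pin (inclusive at 0.90; ties between
references resolve to list order). Tanimoto of two empty bit sets is
defined as 0.

Classification replaces manual curation with twelve ordered substructure
rules (first match wins). Rule order resolves scaffold containment:
coumestan (ring lactone + aromatic five-ring oxygen) fires before coumarin;
naphthoquinone and coumarin before flavonoid; curcuminoid before chalcone
before stilbene before the hydroxycinnamic patterns; aryl-carboxylic acid
(phenolic acid) and the phenol/aryl-ether fallback (hydroxybenzene) come
last before "other". Patterns are written against RDKit's perceived
aromaticity, in which fused 2H-pyranones (coumarins, chromones) come out
aromatic. Glycosylated or otherwise conjugated polyphenols classify by
their aglycone scaffold, since the rules target cores, not decorations. The
packaged reference list carries one prototypical member per class — the
"other" prototype is mandelic acid, chosen because it is a documented
unclassifiable polyphenol-adjacent hit that no scaffold rule can claim —
plus a few frequently encountered compounds; it is a compact stand-in for a
full polyphenol catalogue, so absolute match counts on real screens will
differ from any published census.

## Atom typing

Protein atoms are typed from shipped per-residue templates
(`data/protein_atom_types.tsv`, editable): backbone N/CA/C/O/OXT →
N.am/C.3/C.2/O.2/O.co2 with context `bk`; side chains per residue (Ser
OG/Thr OG1/Tyr OH → O.3; Asp/Glu carboxylates → O.co2; Arg NE/NH* → N.pl3;
Lys NZ → N.4; His and Trp ring nitrogens → N.ar; aromatic ring carbons →
C.ar). His ring nitrogens are typed N.ar uniformly; protonation is not
modelled. Ligand and cofactor atoms are typed from geometry alone: bonds
from covalent radii (+0.40 Å tolerance), aromatic rings from 5/6-ring
planarity (RMS out-of-plane < 0.15 Å), degree ≤ 3 and mean ring bond length
< 1.45 Å, carboxylates from a carbon bearing two terminal oxygens, carbonyl
vs hydroxyl oxygen from the C–O bond length (< 1.30 Å → double). This works
on heavy-atom-only crystal input; polar hydrogens are typed only when
present, and no hydrogens are ever added.

## Pair distribution functions

Typed ligand-atom × site-atom distances within 7.5 Å are binned at 0.1 Å
(right-closed bins). The normalized profile is
`g_ij(r) = p_ij(r)/(4πr²bN) − g_ab(r)` with `r` the bin center. Two
readings of `N` exist; the default interprets `N` as the per-type-pair
total `N_ij` in the first term and as the type-blind total `N_all` inside
the background `g_ab`. This choice makes rare and abundant pairs comparable
on one scale and yields two exact identities the tests assert: a
single-type system has `g ≡ 0`, and the count-weighted sum
`Σ (N_ij/N_all)·g_ij(r)` vanishes in every bin. A `global` switch
normalizes everything by `N_all` instead. Profiles are scale-invariant
under count duplication, so pooling structures (binwise count sums before
normalization) is well defined. Pair counts are heavy-atom ligand × site
only; no intra-ligand or intra-protein pairs.

## Interaction detectors

The seven detectors use the published default thresholds of geometric
single-structure profilers, all exposed on `ProfilerConfig`: hydrogen bonds
at donor–acceptor 2.5–4.1 Å (donor angle ≥ 100° when hydrogens exist;
distance-only otherwise), hydrophobic contacts between apolar carbons (not
bonded to N/O) at ≤ 4.0 Å with the closest contact kept per (residue,
ligand atom), π-stacking at centroid distance ≤ 5.5 Å and lateral offset
≤ 2.0 Å with parallel ≤ 30° and T-shaped 60–90°, π-cation at ≤ 6.0 Å from
the ring centroid to Lys NZ / the Arg guanidinium centroid (His only when
configured cationic), salt bridges between opposite-signed group centers at
≤ 5.5 Å (ligand carboxylate midpoint vs Asp/Glu/Arg/Lys centers), metal
coordination at metal–O/N ≤ 3.0 Å with the coordination number reported
descriptively (4 → tetrahedral-like, 5 → trigonal-bipyramidal-like, 6 →
octahedral-like), and single-water bridges where one water oxygen is
H-bond-compatible (2.5–4.1 Å) with polar atoms on both sides.

Two refinements (on by default) prevent double counting: hydrophobic
contacts whose atoms all belong to a detected π-stack are dropped, and
hydrogen bonds whose partners both sit inside the charged groups of a
detected salt bridge are dropped. Covalent ligand–protein links are not
detected; every contact is profiled as noncovalent.

Records sort deterministically by (residue, kind, distance). Class
summaries report count, mean ± sd of distance and angle, and relative
frequency per class (frequencies sum to 1 over kinds within a class).
Trajectory profiling re-extracts the binding site per frame and reports a
boolean (residue, kind) × frame presence matrix with occupancies.

## Hydrogen-bond networks

Network H-bonds use donor–acceptor ≤ 3.5 Å. With hydrogen coordinates the
angle criterion requires the deviation of D–H···A from linearity to be
≤ 60° (i.e. ∠DHA ≥ 120°) — the common convention in H-bond graph tools; a
switch is not provided because the deviation reading is also what the
planted fixtures encode. Candidate pairs come from a k-d tree
(`scipy.spatial.cKDTree.query_pairs`), contractually a superset of all
pairs within the radius, so the resulting bond list equals the all-pairs
computation at sub-quadratic expected cost.

Nodes are residue side chains, residue backbones, and ligand polar groups
(carboxylate oxygen pairs merge into one group; other polar atoms are their
own group). Waters are path-interior only. Bridges are shortest chains of
1–3 distinct waters found by breadth-first search, which guarantees simple
paths; per frame the minimum water count per node pair is kept, and one
witness path is reported so the criteria can be replayed. Over a
trajectory, an edge's occupancy is the fraction of frames with any
qualifying path and `mean_waters` averages the per-frame minimum over the
frames where the edge is present; direct and water-mediated edges are
tracked separately (a direct edge always has zero waters). The default
reporting filter keeps edges with occupancy ≥ 0.5; pass 0 to keep all.

## Conserved waters

Snapshots are rigid-body superposed (Kabsch, numpy SVD, proper rotation
enforced) on an index-matched selection — by default all protein atoms —
and the fitted transform moves all atoms including waters. Sequence-aware
structural alignment across different topologies is out of scope. Pooled
water oxygens are clustered with a hand-implemented classic DBSCAN
(ε = 0.9 Å presumed Ångström, min_pts = 4 — the 3D convention; core points
count themselves). Points are processed in storage order, so a border point
reachable from two clusters joins the first-discovered (lowest-index) one;
this canonical tie-break is why DBSCAN is implemented here rather than
delegated, and the tests cross-check the labels against both a textbook
brute-force oracle and scikit-learn's implementation. Conservation is
cluster size divided by the number of snapshots; it may exceed 1 when one
snapshot contributes several waters to a site (logged, not capped). The
default report keeps clusters with ≥ 16 members and conservation > 0.26 —
thresholds that are mutually consistent at 61 snapshots (16/61 ≈ 0.262).

## Trajectory utilities

RMSD uses optimal superposition per frame. Frame clustering is
average-linkage agglomerative clustering (scipy) of the pairwise RMSD
matrix cut at a requested cluster count, with clusters relabelled by first
appearance; the medoid is the member with minimal summed within-cluster
RMSD, ties to the lower frame index.

## Synthetic data: what it shows and what it does not

The generators build minimal idealized fragments — perfect 1.39 Å benzene
hexagons, lone side chains without full backbones, colinear water chains —
at exactly controlled geometry, with the planted truth serialized next to
the data. Defaults encode the study conditions the package is verified
under: a 200-frame bridge trajectory with a two-water chain present in 70 %
of frames; three Gaussian water blobs (σ = 0.3 Å, 40 points each) in 100
uniform noise points within a 20 Å box; a 61-snapshot convention for the
conservation arithmetic. Every generator is a pure function of its
parameters and seed.

Passing tests on these fixtures demonstrate the geometric and statistical
machinery: detectors fire exactly on planted geometry, occupancy estimation
is unbiased, cluster recovery is pure at the planted separation. They do
not demonstrate robustness to the messiness of real data — missing atoms,
alternate conformations beyond simple altlocs, distorted rings, protonation
ambiguity, or force-field-specific water behaviour — and the packaged
reference list is far smaller than any real polyphenol catalogue, so
screening counts on real inputs carry no calibration from these tests.

## Degenerate inputs and numerical conventions

Rings whose atoms are nearly collinear (second singular value < 10 % of the
first) are skipped with a log message. Empty trajectories, zero or negative
bin widths, mismatched binnings, selection mismatches and out-of-range
thresholds raise `ValueError`; a missing ligand raises `LookupError`; a
missing model raises `IndexError`. Bin assignment is right-closed
(`edges[k] < d ≤ edges[k+1]`), so a pair exactly at the cutoff counts.
Occupancy of a planted fraction q over n frames is `round(q·n)/n` by
construction. All stochastic tests run with fixed seeds; hypothesis
property tests run derandomised.

## Problem sizes

Test fixtures use ≤ 300 atoms or points per oracle comparison, 200-frame
trajectories and 20-seed repetition studies; the full suite and the
acceptance script each complete in seconds. These sizes are the package's
verification conditions, chosen so that exhaustive brute-force oracles
remain exact and cheap.
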