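# Methods

This note documents the models implemented in prnkit, the defaults and their
rationale, the numerical choices, and what the synthetic test data does and
does not establish about real proteins.

## Network models

**Nodes.** Each residue of the PDB file is one node, identified by
`(chain, number, insertion code, name)` and labelled
`chain:number[:icode]:name`. Numbering is taken exactly as printed (no
renumbering); only the first model of multi-model files is read; alternate
locations resolve to the highest-occupancy conformer (ties by altloc letter,
so parsing is deterministic). Waters are dropped by default; other HETATM
residues (ligands, nucleic acids, saccharides) become nodes when
`include_het` is set. Numbering gaps per chain are recorded, since a gap is
a natural place to split a single chain into formal "monomers". When the
energy source is an FMO calculation the nodes are FMO fragments; for
amino-acid fragments the backbone C,O atoms belong to the neighbouring
fragment, so the fragment↔residue correspondence is by identity, not by atom
content (`FragmentMap.offset_note`).

**Edges.** A D-PRN accepts a residue pair when the centre-of-mass distance
R_ij ≤ R_lim (mandatory criterion); the weight is R_ij itself. A PIE-PRN
accepts a pair when the chosen energy term satisfies E ≤ E_lim — the only
mandatory criterion; R_lim is an optional secondary gate — and weighs the
edge 1/|E|. The acceptance comparison is signed for every term, including
PIEDA terms that are typically positive (exchange repulsion): selecting
repulsive interactions is the job of the interface-matrix sign filter, not
of the edge criterion. Edge importance is defined as 1/weight throughout.
Sequence-adjacent (peptide-bonded) pairs are ordinary edge candidates when
`include_covalent` is set (the default), else skipped. Centre-of-mass
distances include hydrogens whenever the file contains them; masses come
from a fixed internal IUPAC table, with the element inferred from the PDB
element column and falling back to the first alphabetic character of the
atom name.

Where both a secondary R_lim and a PIE criterion apply, the distance is the
centre-of-mass distance, consistent with the D-PRN definition (closest-atom
distance is a plausible alternative; COM was chosen for consistency).

## Energy sources

**FMO.** The parser locates the two-body pair-interaction table by a
tolerant regular expression on the section header, reads rows
`I J E_tot [ES EX CT DI [SOLV]]`, and converts Hartree → kcal/mol
(× 627.5095) unless the section carries an explicit kcal unit tag. Duplicate
pair entries with conflicting energies are an error. Abinit-MP / PAICS
outputs are rejected. Both solvent-screened and bare tables are simply
whatever the file prints; no recomputation or correction is attempted.

**Force field.** Residue-pair energies are bare pairwise sums over the
static structure — no cutoff, no periodic images, no minimisation — because
the model is the structure exactly as deposited. For atoms a ∈ residue i,
b ∈ residue j:

* elec = Σ k_e q_a q_b / r_ab with k_e = 332.0636 kcal Å mol⁻¹ e⁻²
  (prmtop charges are divided by 18.2223 to recover elementary charges);
* vdW = Σ A_ab/r¹² − B_ab/r⁶ with the pairwise Lennard-Jones coefficients
  from the topology (equivalently ε_ab(Rmin_ab/r)¹² − 2ε_ab(Rmin_ab/r)⁶);
* pairs separated by one or two bonds are skipped; three-bond (1-4) pairs
  are divided by SCEE = 1.2 (electrostatics) and SCNB = 2.0 (vdW), read
  from the topology when present.

Bonded separations are derived from the bond graph by breadth-first search
(shortest bond path decides; a ring pair that is both 1-3 and 1-4 counts as
1-3), rather than from the topology's exclusion/dihedral lists — equivalent
for ordinary molecules and independently checkable. The prmtop reader is a
minimal in-package implementation covering the charge/LJ/bond sections;
10-12 potential slots (negative nonbonded index) are treated as "no LJ".

## Network measures

Weight semantics: weight = distance for shortest-path-based measures
(closeness, betweenness, efficiency, paths); importance = conductance /
coupling strength for current-flow betweenness, modularity and spectral
clustering. Closeness uses the Wasserman–Faust within-component convention
scaled by (component size − 1)/(n − 1); current-flow betweenness is computed
per connected component (zero on components of fewer than three nodes,
where no intermediary exists).

The total-energy centrality is C_k^Etot = Σ E_tot over the node's incident
edges; it needs a PIE-PRN and is refused on distance networks.

The weighted global efficiency is E_glob = ⟨1/d(i,j)⟩ over ordered pairs,
with 1/d = 0 for disconnected pairs; local efficiency of node k is E_glob of
the subgraph induced by k's neighbours (zero with fewer than two
neighbours). The efficiency centrality is the relative efficiency drop on
node removal, C_k^eff = (E_glob(G) − E_glob(G−k))/E_glob(G); the cited
formulation leaves details open, so this definition is fixed here and
oracle-tested against independent shortest-path computations. It can be
negative for peripheral nodes.

Shortest paths minimise total edge weight, with ties broken by lexicographic
node sequence so reports are reproducible. Louvain runs on edge importance
with resolution 1.0 and an explicit seed; community indices are renumbered
by smallest member label. Spectral clustering takes the k eigenvectors of
the smallest eigenvalues of the importance-weighted normalized Laplacian,
row-normalises them and groups with seeded k-means; k = 1 and k = N
short-circuit to the trivial partitions.

**Folding degree.** The per-residue folding index is built from backbone
dihedral angles: for each chain the N–CA–C atoms in residue order define
consecutive dihedrals θ_i; the tridiagonal matrix B with B_ii = cos θ_i and
B_{i,i±1} = 1 (adjacent dihedrals share a bond) is exponentiated and each
residue receives the mean of diag(exp B) over the dihedrals its atoms take
part in. The score depends only on dihedrals, hence is rigid-motion
invariant, and is larger for folded (helical, θ near 0°) than for extended
backbones. The tests are property-based (invariance, helix > strand,
short-chain rejection), as the index has no closed-form reference values.

## Interface suite

`split_supersystem` partitions the edges of G into G_A, G_B and the
bipartite G_PPI (only cross-monomer edges, only nodes touching one);
G_{A∪B} keeps all nodes and drops exactly the interface edges. NDA is
ΔC_k = C_k(G) − C_k(G_{A∪B}) for any centrality kind. For the total-energy
kind the difference reduces in closed form to the sum of the node's
cross-monomer edge energies (the intra-monomer terms cancel), and it is
evaluated that way so the identity holds bit-exactly in floating point; a
test verifies agreement with the generic subtraction route. The
monomer-graph baseline (subtracting C_k computed in G_A or G_B) is retained
behind a flag but flagged as size-inconsistent: centralities are not
directly comparable between graphs of different size.

The SVD decomposes the interface matrix with σ descending; the sign
ambiguity of singular pairs is resolved by making the largest-magnitude
entry of each left vector positive, so motif reports are reproducible. The
convergence factor is the partial singular-value sum f^(r) = Σ_{i≤r} σ_i /
Σ_i σ_i. Dominant motif nodes are those within α (default 0.5) of the
motif's largest component magnitude. SPIE tables and binding energies read
from the raw pair-energy table rather than the thresholded graph, because
repulsive cross pairs — excluded by any attractive edge criterion — are
part of both analyses. Binding-energy partitioning is a pair sum only; no
many-body or deformation corrections are included.

## Synthetic data

The toy-complex generator emulates the geometry of a short helix docked
against a larger partner: two parallel pseudo-chains of three-atom residues
(N/CA/C analogues) at 6 Å spacing, with a seeded subset of index-matched
cross pairs planted 5 Å apart and all other cross pairs at 20 Å. The
margins guarantee that at the manifest's 6 Å centre-of-mass cutoff the
planted pairs are exactly the cross-chain contacts, regardless of the
±0.15 Å coordinate jitter. The pair-energy generator plants attractive
cross energies of magnitude `energy_scale` (default 8 kcal/mol, a strong
salt-bridge-scale interaction), peptide-like −3 kcal/mol on sequence
neighbours, and a deterministic PIEDA-style split (positive exchange term,
the attractive remainder divided 50/20/30 between ES/CT/DI). Energies are
rounded to six decimals so the pseudo-FMO text round-trips exactly. Toy
topologies use two Lennard-Jones types with Lorentz–Berthelot combination
and random charges in ±0.8 e.

These fixtures exercise parsing, construction and every analysis with known
ground truth, but they are not physically realistic: no side chains, no
secondary structure, no solvation, and energies unrelated to the geometry
beyond the planted contacts. Passing tests therefore demonstrate
correctness of the algorithms and formats, not predictive power on real
complexes — applying the toolkit to a real system requires a real structure
and a real FMO or force-field energy calculation.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small systems
(≤ 16-residue complexes, ≤ 8-node random graphs, ≤ 18-atom topologies) so
that exhaustive oracles — full path enumeration, all set-partitions of six
nodes, brute-force atom-pair double loops — stay tractable; all algorithms
are size-independent. Every stochastic component (fixture generation,
Louvain, k-means) takes an explicit seed, reports are written with fixed
%.6f formatting, and the batch pipeline is byte-reproducible for a given
seed. Degenerate inputs are errors, not silent results: empty graphs,
all-zero interface matrices, zero-mass residues, sub-3-node efficiency
centralities and chains too short for dihedrals all raise with a message.
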