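# Methods

## The problem

A point mutation at a protein–protein interface changes the binding free
energy of the complex by ΔΔG = ΔG(mutant) − ΔG(wild-type), in kcal/mol
(positive values weaken binding; from dissociation constants,
ΔG = RT ln K_d with R = 1.9872×10⁻³ kcal/(mol·K)). `topoddg` predicts ΔΔG
from structure alone by converting the local geometry of the mutation site
and the binding interface into persistent-Laplacian spectral features and
regressing those features against measured ΔΔG. A second, independent part
of the package quantifies how far a *predicted* complex structure deviates
from its experimental reference, and where: whole-complex superposition
RMSD, per-residue backbone RMSD joined with crystallographic B-factors, and
summaries of predictor confidence scores (ipTM/pTM).

## Atom subsets and the modified distance

Featurization never sees a whole complex; it sees four heavy-atom subsets:

* the mutated residue's atoms (the mutation site),
* all atoms within `r_neighborhood` of any mutation-site atom (default
  10 Å; distance to the site is the *minimum* over site atoms, which makes
  the subset monotone in r),
* each partner's atoms within `r_binding` of any atom of the other partner
  (default 12 Å).

Subsets are intersected with element groups; the default roster is all six
unordered pairs over {C, N, O}. C–C pairs probe hydrophobic packing, N/O
pairs probe polar contacts. Hydrogens are never present (heavy-atom point
clouds), and alternate conformations are reduced to the highest-occupancy
conformer so each atom has exactly one position.

Within one subset pair the two sides play the roles of group P1 and group
P2 (the two binding partners for interface subsets; mutation-site vs
neighborhood atoms for mutation-centric subsets). The *modified distance*
assigns +∞ to same-group pairs and the Euclidean distance otherwise, so
that filtration topology is created only by cross-group interactions — the
physically interesting ones.

## Filtrations, boundary operators, Laplacians

Dimension-0 features use a Vietoris–Rips filtration over the (modified)
distance matrix: a simplex enters at its diameter, and an infinite pair
never co-occurs in a simplex. Dimension-1/2 features use the Alpha complex
of the subset's coordinates: a subcomplex of the Delaunay triangulation
whose filtration values we assign by the standard rule — a simplex whose
circumsphere is empty (Gabriel) enters at its circumradius, any other
simplex inherits the smallest value among its cofaces — reported on the
radius scale in Å. The two scales (diameter vs radius) are never mixed
within one feature block. Because the Alpha complex is built from raw
coordinates, the same-group exclusion is applied afterwards by pruning
every simplex that contains a same-group vertex pair (vertices always
survive; with two groups this removes all simplices of dimension ≥ 2,
leaving the cross-group bipartite graph — the down-Laplacian still carries
dimension-1 spectra).

For a snapshot K(t) of the filtration, the signed boundary matrices B_k
(orientation fixed by ascending vertex index, sign (−1)^i on the face
dropping the i-th vertex) define the combinatorial Laplacians

    L_k = B_{k+1} B_{k+1}ᵀ + B_kᵀ B_k,      L_0 = B_1 B_1ᵀ.

L_k is symmetric positive semidefinite; the multiplicity of its zero
eigenvalue equals the Betti number β_k (components, loops, cavities), and
the non-zero spectrum carries additional shape information. Spectra are
independent of the orientation convention.

The p-persistent variant couples K(t) to K(t+p): the up-part is built from
the (k+1)-chains of K(t+p) whose boundary lies in the k-chain space of
K(t). That subspace is computed as an explicit orthonormal null-space
basis of the "outside rows" block of B_{k+1}(K(t+p)) — numerically robust
at the matrix sizes used here and directly checkable against rank-based
oracles — rather than via a symbolic Schur complement. At p = 0 the
construction short-circuits to the plain combinatorial Laplacian and the
equality is exact entrywise.

## Feature vectors

Along a fixed grid (defaults: 0–12 Å step 0.25 for dimension 0, step 0.5
for dimensions 1–2; p = one grid step, configurable down to p = 0), each
(subset pair, dimension, grid value) contributes eight numbers: the
harmonic multiplicity, then min/max/mean/std/sum/variance of the
non-harmonic eigenvalues, and a flag marking whether any non-harmonic
eigenvalue existed (so an all-zero statistics block is distinguishable from
a spectrum that is genuinely zero). A record's vector is the concatenation
of the wild-type block, the mutant block, and their difference — ΔΔG is a
difference quantity, and the explicit delta channel spares the learner from
reconstructing it. An `extra` slot appends externally computed per-residue
embeddings verbatim; nothing of that kind is computed in-repo.

When no modelled mutant structure is supplied, the fallback mutant is
side-chain truncation: backbone + CB retained (CB dropped for glycine) and
the residue renamed. This is deliberately crude — no repacking — and is
intended for testing and for quick screens.

Three exact invariances follow from the construction and are enforced by
tests: rigid motions of the complex, atom order in the input file, and
locality (atoms beyond the subset radii cannot affect the vector). The
geometric invariances hold for point sets in general position; exactly
cospherical points (they occur in idealized synthetic geometry, not in
experimental coordinates) can make the floating-point Delaunay
triangulation, and hence dimension-1/2 features, tie-break differently.

## Regression and validation metrics

The regressor is a gradient-boosted tree ensemble
(`sklearn.GradientBoostingRegressor`; 500 trees, learning rate 0.05, depth
3, subsampling 0.8) whose boosting starts from a ridge fit (`init=Ridge`).
The linear initialization is a deliberate design choice: spectral-statistic
features carry strong near-linear components, and pure tree ensembles
approximate smooth additive signals poorly — on a sparse linear target
they plateau at roughly 1.7× the noise floor, while ridge-initialized
boosting reaches it. Trees then model what the linear baseline cannot.
`linear_init=False` restores a pure tree ensemble.

Model quality is reported as the Pearson correlation R_p and RMSE
(kcal/mol) over *pooled* out-of-fold predictions of a 10-fold
cross-validation with seeded uniformly random folds. Because curated
mutation sets repeat complexes and contain forward/reverse pairs with
negated ΔΔG, grouped fold assignment is available (`complex` keeps a
complex's mutations together; `mutation-pair` keeps a mutation and its
reverse together); default is per-record assignment, and results should be
read per grouping mode.

## Structural evaluation

Chains of the predicted complex are mapped to reference chains by global
sequence alignment identity, scoring all bijections when the chain count
allows it and breaking exact ties (homodimers) by the lower whole-complex
RMSD; a reference chain with no candidate above 30% identity is an error.
The superposition is a least-squares Kabsch fit (proper rotation, SVD with
determinant correction) on the Cα atoms of all mapped chains jointly —
the complex is aligned as one rigid body, not chain by chain — with a
backbone-atom variant available since published RMSDs vary by convention.
Per-residue RMSD uses the backbone atoms (N, CA, C, O) present in both
structures, residues paired per chain by global sequence alignment so that
point differences and missing loops pair correctly. The per-residue table
is joined with mean backbone B-factors as the flexibility proxy.

Batch summaries report mean RMSD/ipTM/pTM, the fractions in the standard
confidence bands (ipTM ≥ 0.8 highly confident, ipTM < 0.6 likely
incorrect, pTM ≥ 0.5 globally plausible; an RMSD above 4 Å is exposed as
the outlier constant, not hard-coded logic), the top-N lists by highest
RMSD and lowest ipTM with lexicographic tie-breaks, and their
intersection — complexes poor by both measures.

## Synthetic data: what it emulates and what it does not

The toy dimer is two idealized helical chains (backbone + CB, ~100°/turn,
1.5 Å rise) with a controlled interface: the first `interface_contacts`
residues of chain B are guaranteed cross-partner atoms within 5 Å and the
rest veer away; zero contacts means fully separated chains. Synthetic
B-factors rise quadratically toward the termini. The perturbation operator
displaces each residue along a random direction scaled by a per-residue
amplitude profile, optionally composed with a random rigid motion — the
mechanism by which flexible regions become mis-modelled regions. The
mutation-dataset generator draws standard-normal features and a ΔΔG that
is a known sparse linear function of them plus Gaussian noise, optionally
with exact reciprocal (negated) pairs.

These generators provide geometry, not energetics: no side-chain packing,
no chemistry in the contact pattern, and the linear effect model is far
simpler than real mutation thermodynamics. Passing the validation suite
therefore demonstrates that the mathematical machinery is correct and that
the pipeline recovers a known signal under its own assumptions — it does
not certify accuracy on experimental mutation data, which requires the
full curated dataset and modelled mutant structures.

## Numerical choices

* Harmonic threshold: an eigenvalue counts as zero below
  1e-8 × max(1, λ_max) — scale-relative, so unit changes are harmless.
* Dense `eigh` for all spectra; matrices above 2,000 simplices are
  rejected rather than silently switched to extremal iterative solvers,
  because the statistics need the full spectrum.
* Degenerate (collinear/coplanar) point clouds are joggled for the
  Delaunay step, with a warning; ≤ 4 points are handled directly (the full
  simplex is its own triangulation).
* Betti oracles use numpy integer matrix ranks of the ±1 boundary
  matrices; at the enforced matrix sizes the rank tolerance is safe by a
  wide margin.
* Tie-breaks in rankings are lexicographic on complex id; fold assignment
  shuffles with `numpy.random.default_rng(seed)`.
* SKEMPI-style tables: multi-point mutations and rows missing either
  affinity are dropped (and counted); duplicate (complex, mutation)
  measurements are averaged; unparseable temperatures fall back to 298 K
  with a warning.

## Reference validation conditions

The shipped validation suite and `scripts/acceptance.py` use problem sizes
chosen to exercise every code path while staying desk-scale: 300–500
random point clouds of ≤ 12 points with five snapshots each for the
boundary/Hodge checks; 1,000 random rigid motions for the Kabsch check; a
60-residue-per-chain dimer for the B-factor/RMSD mechanism; n = 500
(d = 20, 5 active coefficients, σ = 0.3 kcal/mol) for parameter recovery
with an n = 1,000 shuffled-target control; and 72 featurized toy mutations
for the end-to-end run in which ΔΔG is a known function of the topological
features themselves.

## Known limitations

* The fallback mutant builder cannot represent side-chain rearrangement;
  supply modelled mutant structures for serious use.
* With two groups, pruning leaves no simplices of dimension ≥ 2, so
  dimension-2 blocks are informative only under euclidean (unpruned)
  configurations or >2-group labelings.
* The persistent up-part costs a dense null-space per grid point; with the
  default grids this is comfortable for interface subsets of a few hundred
  atoms but not for whole-proteome scans. Set `persistence_steps=0` or
  coarsen the grid for large batches.
* Chain mapping assumes sequence identity is informative; engineered
  chimeras below 30% identity to their reference need a manual map.
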