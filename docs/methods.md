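# Methods

This note records the models, conventions and numerical choices behind
`allodyn`, and what the synthetic studies do and do not demonstrate.

## Coordinates, numbering, selections

All coordinates are in Ångström.  Residue numbering is PDB author numbering
throughout — residues are addressed exactly as printed in the structural
literature (D590, K579, E755, T739, W557, D638, D742 for the GR ligand-binding
domain) and never renumbered internally.  Selections use the MDAnalysis
selection language (`"chain"` is accepted as an alias for `"chainID"`); a
selection always resolves to a deterministic, file-ordered index set, and an
empty result is an error, never a silent empty analysis.  Alternate locations
keep altloc blank or "A"; insertion codes are rejected with a clear error.
Multi-model PDB is the canonical ensemble format; DCD is supported behind the
same `Ensemble` contract when a PDB topology is supplied.

## Superposition, RMSD, RMSF

Frames are fitted by mass-unweighted least squares (Kabsch, SVD with a
determinant correction so the rotation is always proper — the fit can never
mirror a structure; near-collinear fit sets are rejected as ill-posed).
Non-fit atoms are carried along by the same transform.  RMSD is reported over
the fit selection by default, with a separate analysis selection available;
RMSF is the root-mean-square deviation of each atom about its time-mean
position and requires at least two frames.  The default RMSD/RMSF selection is
all receptor-chain Cα atoms.

## DCCM

The covariance is the scalar (dot-product) form over superposed positions,
`c_ij = <r_i·r_j> − <r_i>·<r_j>`, normalised to `C_ij = c_ij /
(c_ii c_jj)^{1/2}`.  Nodes are Cα atoms only; there is no mass weighting.
Zero-variance nodes are masked (NaN) with a warning and propagate as missing —
never as zero correlation — into the network stage.  Entries are clamped to
[−1, 1] only against floating-point overflow (a pre-clamp excess beyond 1e−12
is an error).  With several replicas, the per-replica DCCMs are averaged
elementwise by default; pooled concatenation is available by flag and the
chosen mode is recorded in the run manifest.

A caveat worth knowing: global least-squares fitting redistributes coherent
collective motion.  Subtracting the best-fit rigid transform induces a small
negative correlation of order −2/R between independent residues (R = number of
fitted atoms) and attenuates planted pair correlations by roughly 2(1+ρ)/R.
The planted-recovery study therefore uses a receptor-sized system (257
residues), where the distortion (~0.01) is far below the 0.05 acceptance
band; on very small systems the effect is visible and expected.

## Residue interaction network

Nodes are residues.  Contact uses the minimum heavy-atom distance by default
(Cα distance by flag); a pair is an edge iff it is within 4.5 Å in at least
75 % of frames (inclusive cutoff).  Sequence neighbours with |i−j| ≤ 1 on the
same chain are excluded (configurable) to suppress trivial backbone edges.
Edge weights are `d_ij = −ln|C_ij|`; natural log is the default (the method
lineage writes "−log" without a base; base 10 is available by flag).  Edges
with |C| = 0 are dropped as infinitely distant; edges whose correlation is
masked are dropped with a warning.  Path lengths are reported both as raw
weighted sums and as ×100-rounded integers, since published path tables use a
scaled-integer convention; the manifest names which convention a comparison
uses.

Communities come from the Girvan–Newman hierarchy: edges are removed in order
of weighted edge betweenness (weights treated as distances), and the partition
kept is the one maximising modularity computed with |C| as the affinity
weight.  Ties in betweenness are broken toward the lexicographically smallest
edge and modularity ties toward fewer communities, so the output is
bit-stable.  Inter-community connectivity counts, for every node pair, how the
deterministic all-pairs shortest path (Floyd–Warshall, strict-improvement
updates, intermediates scanned in sorted order) crosses community boundaries.
Suboptimal paths enumerate all simple paths within a length tolerance δ of the
optimum (default δ = 0.20 raw weight = 20 in ×100 units) by depth-first search
pruned with single-source shortest-path lower bounds, sorted by length then
lexicographic node order.

## Pocket geometry and landscapes

Triangle collective variables use the Cα positions of the three named
residues by default (the marker atom is configurable); the area is half the
cross-product magnitude of two edge vectors and is rigid-motion invariant.
Hydrogen bonds use a pure distance criterion — formed iff donor–acceptor
heavy-atom distance ≤ 3.5 Å, inclusive, with no angular term.  Which ligand
atom pairs with the receptor threonine hydroxyl is configuration, not code:
conserved-atom choices differ per ligand and both published variants are
expressible.  Distance densities default to Freedman–Diaconis histograms;
Gaussian KDE with Silverman bandwidth is optional, and an all-identical series
under KDE falls back to a delta-like histogram with a warning.  The 2D
free-energy landscape is `F = −kT ln(P/Pmax)` over a 50×50 histogram (default)
spanning the observed CV range padded 5 %, at 300 K (k_B = 0.0019872
kcal·mol⁻¹·K⁻¹, matching a standard simulation thermostat temperature); empty
bins are masked, never −kT ln 0.  Replicas are pooled by default for
landscapes; per-replica landscapes are a flag.

## Interaction energetics

Single-trajectory end-point decomposition between two atom groups sharing the
same frames:

    ΔG_bind = ΔE_MM + ΔG_solv,   ΔE_MM = ΔE_vdw + ΔE_ele + ΔE_int,
    ΔG_solv = ΔE_polar + ΔE_nonpolar

The entropic −TS term is omitted (appropriate when comparing similar systems),
and ΔE_int ≡ 0 because intramolecular bonded terms cancel in single-trajectory
mode; the field is kept so the decomposition table retains its conventional
rows.  Lennard-Jones uses `ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶]` with
Lorentz–Berthelot combining; Coulomb uses k_e = 332.0637 kcal·Å·mol⁻¹·e⁻² over
an interior dielectric (default 1).  No nonbonded cutoff is applied by default
(group sizes are desk-scale).  Atom pairs closer than 0.1 Å abort with the
offending pair named.

The polar solvation term is a pairwise Generalized Born model with fixed,
user-supplied Born radii: `f_GB = sqrt(r² + a_i a_j exp(−r²/(4 a_i a_j)))`,
prefactor −k_e(1/ε_in − 1/ε_solv), solvent dielectric 80.  This is a
deterministic, desk-scale continuum model that preserves the standard
decomposition structure; outputs label the term ΔE_polar(GB).  Its limits are
exact: zero at equal dielectrics, the Born self-energy at r = 0, screened
Coulomb at large separation.  SASA is an in-package Shrake–Rupley with
golden-spiral sphere points (default 960 for standalone calls, 240 inside the
per-frame decomposition), probe 1.4 Å; a test point is buried iff strictly
inside a neighbour's expanded sphere, so exactly coincident identical atoms do
not occlude each other (tie rule, regression-locked).  The nonpolar term is
`γ·SASA + b` per species (γ = 0.00542 kcal·mol⁻¹·Å⁻², b = 0.92 kcal/mol),
combined as complex − receptor − partner.

Per-residue attribution covers the residues of both partners: every cross-pair
energy splits half-and-half between the two residues it connects (the Amber
decomposition convention), SASA differences are attributed to each atom's own
residue, and the constant offset b — owned by no residue — is spread equally
across rows.  Consequently rows sum to the corresponding totals exactly, which
the tests enforce at 1e−6.  Means and standard deviations are over (strided)
frames.  Parameters come from a documented TSV (serial, charge, LJ Rmin/2, LJ
ε, Born radius); importing simulation-package topology files is a non-goal.

## Frame clustering

Features are flattened Cartesian coordinates of the selection after
superposition (the cpptraj convention).  k-means++ seeding and Lloyd
iterations run through scikit-learn with n_init = 1 and a fixed random state,
so results are deterministic per seed; empty clusters are re-seeded from the
farthest points (the library's relocation rule).  k is user-chosen (default 5
in the pipeline configuration shipped here as 3 for the small toy), with an
inertia-vs-k elbow report written alongside; the run manifest records the
choice.  The representative structure of a cluster is the member frame whose
selected coordinates are nearest (Euclidean) to the centroid.

## Synthetic studies: what they emulate and what they do not

The generator produces a deterministic toy complex — a helix-like Cα trace
with one side-chain pseudo-atom per residue (twist 100°, rise 0.9 Å, chosen so
the (i, i+3) and (i, i+4) contacts of a real helix are reproduced under the
4.5 Å gate), an optional 5-atom ligand in the helix pocket, and an optional
5-residue peptide whose L-R-A-L-L motif docks its arginine against the
receptor aspartate analogue, so LXXLL-style relative labels (L+1…L+5, R+2)
resolve and the energetics stage has a planted salt bridge.  Residue
displacements are drawn from a zero-mean multivariate normal with a planted
residue-level correlation matrix applied identically and independently on x,
y and z — exactly the structure under which the scalar dot-product DCCM
recovers the planted values in expectation.  Each frame then receives
rigid-body jitter (default ±1 Å, ±5°), which superposition removes again.
One seeded numpy Generator stream drives everything; the seed is recorded in
the truth manifest.

Planted matrices that are indefinite (e.g. a correlation chain with only
consecutive links set) are repaired by clipping negative eigenvalues at zero
and rescaling the diagonal to one; the repair is always reported, the truth
manifest stores the matrix actually sampled from, and recovery is measured
against it.

Two preset studies define the standard conditions:

* **Path study** — 40 receptor residues, a chain 602→599→596→593→590 with
  link correlation 0.9 (≈0.75 after PSD repair), σ = 0.5 Å, 600 frames.
  Consecutive chain members are (i, i+3) spatial contacts, so the planted
  chain is exactly the minimum −ln|C| path.
* **Community study** — two compact 8-residue clusters (cube vertices on a
  2 Å circumsphere, every intra-cluster pair within 4.0 Å) bridged by facing
  corners at ~4.3 Å.  Intra-block correlation decays with sequence separation
  as 0.8^|i−j| (an AR(1) profile), zero across blocks; σ = 0.3 Å, 600 frames.
  Two deliberate design points: the clusters are spatially compact so the
  contact graph itself is modular (Girvan–Newman over-splits long band
  graphs), and the correlation profile is decaying rather than flat, because
  a flat equicorrelated block is dominated by a block-translation mode that
  the global rigid fit absorbs and redistributes into intra/cross
  correlations of equal magnitude, destroying the |C| contrast.

What passing these studies shows: the estimators, graph algorithms and
bookkeeping are correct, deterministic, and recover known structure through
the full pipeline.  What they do not show: anything about real receptor
dynamics — the toys have Gaussian, single-basin, solvent-free dynamics with
no anharmonicity, no real force field, and idealised geometry.

## Problem sizes

The shipped test and acceptance runs use desk-scale sizes chosen as the
smallest at which each estimate is statistically clean: 5000 frames for
planted-correlation recovery (sampling error ≈ 0.014), 600 frames for
network/community/path recovery, 257 receptor residues for the
recovery study and 16–40 for everything else, 10⁵ samples for landscape
closed-form checks, and 240 sphere points per atom inside per-frame SASA
(960 for standalone accuracy checks, where the isolated-atom sphere is exact
to 0.5 %).

## Known limitations

* The GB polar term uses fixed input Born radii; no self-consistent radius
  perturbation, and no Poisson–Boltzmann solver.
* Hydrogen bonds are distance-only; no angular criterion.
* Networks are static over the analysed window; no time-windowed variants.
* mmCIF, solvent/ion handling and entropy estimation are out of scope.
* k for clustering and the source/target residues for path analysis are
  user choices recorded in the manifest, not inferred.
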