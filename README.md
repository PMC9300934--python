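# allodyn

Allosteric-communication analysis of conformational ensembles.

`allodyn` implements, as a tested and reusable pipeline, the trajectory-analysis
machinery used to relate ligand-binding-pocket dynamics to cofactor-binding-pocket
dynamics in nuclear receptors such as the glucocorticoid receptor (GR): which
residues move together, how pocket geometry fluctuates, how strongly a cofactor
peptide is held, and along which residue chains correlated motion propagates
between the two pockets.  It is aimed at structural bioinformaticians who have a
conformational ensemble (from MD or elsewhere) and want the standard allostery
tool-chain in one scriptable package — plus a synthetic-ensemble generator with
*planted* ground truth, so every stage can be validated without running any MD.

## What it computes

Given an ensemble of frames over a fixed topology (multi-model PDB, or DCD plus
a PDB topology):

* **Superposition / RMSD / RMSF** — mass-unweighted Kabsch least-squares fit
  (proper rotations only), per-frame RMSD and per-residue RMSF.
* **Representative structures** — k-means (k-means++ seeding, Lloyd iterations)
  over flattened fitted coordinates; the representative of a cluster is the
  member frame nearest its centroid.
* **DCCM** — the dynamic cross-correlation matrix over Cα atoms,
  `C_ij = c_ij / (c_ii c_jj)^(1/2)` with `c_ij = <r_i·r_j> − <r_i>·<r_j>`.
* **Residue interaction network** — nodes are residues; an edge requires a
  minimum heavy-atom distance ≤ 4.5 Å in at least 75 % of frames; edge weights
  are the information distance `d_ij = −log|C_ij|`.  On this graph:
  Girvan–Newman communities cut at maximum modularity, inter-community
  connectivity (shortest-path crossing counts), and optimal plus suboptimal
  source→target paths (Floyd–Warshall with deterministic tie-breaking).
* **Pocket geometry** — atom-pair distance series and densities, hydrogen-bond
  occupancy (distance criterion, ≤ 3.5 Å), triangle-area collective variables
  (e.g. Δ_D590-K579-E755 for the GR cofactor pocket), and 2D free-energy
  landscapes `F = −kT ln(P/Pmax)`.
* **Interaction energetics (MM/GBSA-style)** — single-trajectory binding
  decomposition `ΔG_bind = ΔE_vdw + ΔE_ele + ΔE_int + ΔE_polar + ΔE_nonpolar`
  with a pairwise Generalized Born polar term, own Shrake–Rupley SASA, the
  linear nonpolar model `γ·SASA + b` (γ = 0.00542 kcal·mol⁻¹·Å⁻², b = 0.92
  kcal/mol), and per-residue attribution whose rows sum exactly to the totals.
* **Synthetic ensembles** — deterministic toy receptor–ligand–peptide complexes
  and Gaussian ensembles with a planted residue-level correlation matrix
  (correlated blocks = communities, a high-correlation chain = an allosteric
  path), rigid-body jitter, and a machine-readable truth manifest.

## Worked example

```python
import allodyn
from allodyn.synthetic import path_study_spec

# synthetic study: a high-correlation residue chain planted from resid 602
# (ligand-pocket side) to resid 590 (the cofactor-pocket aspartate analogue)
spec, truth, params = path_study_spec(seed=7, n_frames=600)
ensemble, truth = allodyn.sample_ensemble(spec, truth)
fitted = allodyn.superpose(ensemble, spec.reference, "chain A and name CA")

rmsd = allodyn.rmsd_series(fitted, spec.reference, "chain A and name CA")
print(f"mean RMSD: {rmsd.mean():.2f} A")

corr = allodyn.dccm(fitted, "chain A and name CA")
contacts = allodyn.contact_occupancy(fitted, "chain A")   # 4.5 A / 75 % gate
graph = allodyn.weight_edges(contacts, corr)              # d_ij = -ln|C_ij|
path = allodyn.optimal_path(graph, truth.source, truth.target)
print("optimal path:", " -> ".join(str(r) for r in (n[1] for n in path.nodes)))
print(f"weighted length: {path.length:.3f}  (x100: {path.length_x100})")

motif = allodyn.MotifMapping.from_anchor(fitted.topology, "P", 1)
d = allodyn.distance_series(fitted, "A:590:OD1", "R+2:NE", motif)
print(f"D590(OD1)-R+2(NE) hydrogen-bond occupancy (<= 3.5 A): "
      f"{allodyn.hbond_occupancy(d):.2f}")
```

Output:

```
mean RMSD: 0.84 A
optimal path: 602 -> 599 -> 596 -> 593 -> 590
weighted length: 1.580  (x100: 158)
D590(OD1)-R+2(NE) hydrogen-bond occupancy (<= 3.5 A): 0.77
```

The ensemble fluctuates ~0.8 Å about its reference; the shortest-path search on
the −ln|C| network returns exactly the planted five-residue chain; and the
planted salt-bridge contact between the aspartate carboxylate and the peptide
arginine counts as hydrogen-bonded in 77 % of frames.

## Command line

Each stage is a subcommand over the same YAML configuration (all methods
constants — 4.5 Å / 75 % contact gate, 3.5 Å hydrogen-bond cutoff, γ, b,
300 K — are pre-filled and overridable):

```sh
allodyn simulate --kind path --seed 7 --out fixtures/      # write a fixture
allodyn run --config run.yaml --out results/               # full pipeline
allodyn dccm --config run.yaml --out results/              # one stage
```

Results are TSV/JSON/PDB files under `--out`, registered in a provenance
manifest (`manifest.json`); re-running with the same configuration and seed
reproduces the TSV outputs byte for byte.

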