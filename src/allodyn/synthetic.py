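"""Deterministic toy complexes and stochastic ensembles with planted structure.

Every downstream stage of the pipeline (DCCM, networks, communities, paths,
energetics) is validated against ground truth generated here, so no molecular
dynamics run is needed.  The generator emulates:

* a receptor as an ideal helix-like C-alpha trace with one side-chain
  pseudo-atom per residue, optionally with a small ligand placed in the
  helix "pocket" and a 5-residue coactivator-style peptide whose LXXLL-type
  motif lets relative labels (L+1..L+5, R+2) resolve;
* residue-level displacement fields drawn from a zero-mean multivariate
  normal with a *user-planted* residue correlation matrix (correlated blocks
  play the role of network communities, a high-correlation chain plays the
  role of an allosteric path), applied identically and independently on
  x, y and z so the scalar dot-product cross-correlation recovers the
  planted value exactly in expectation;
* per-frame rigid-body jitter (translation + rotation), removed again by
  superposition, as in real trajectory post-processing.

What it does not emulate: anharmonic/multi-basin dynamics, solvent, real
force-field geometry.  Tests passing here show the analysis machinery is
correct, not that any biological claim holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import AnalysisError, StructureError
from .trajectory import AtomRecord, Ensemble, StructureModel, write_ensemble, write_structure

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "build_toy_complex",
    "plant_correlation",
    "sample_ensemble",
    "write_fixture",
    "read_fixture",
    "community_study_spec",
    "path_study_spec",
]

# Helix geometry: ~100 deg twist per residue; rise tuned so that the
# (i, i+3) and (i, i+4) residue pairs sit inside a 4.5 A heavy-atom contact,
# mimicking the contact pattern of a real alpha-helix.
_TWIST_DEG = 100.0
_RISE = 0.9
_CA_RADIUS = 2.3
_SIDE_RADIUS = 3.8

# Residues with literature roles get real residue/atom names so that
# configurations written in author numbering resolve on the toy.
_SPECIAL_RESIDUES = {
    557: ("TRP", "NE1"),
    579: ("LYS", "NZ"),
    590: ("ASP", "OD1"),
    638: ("ASP", "OD1"),
    739: ("THR", "OG1"),
    742: ("ASP", "OD1"),
    755: ("GLU", "OE1"),
}

# charge (e), LJ Rmin/2 (A), LJ epsilon (kcal/mol), Born radius (A)
_ATOM_PARAMS = {
    "CA": (0.00, 1.9080, 0.1094, 1.70),
    "CB": (-0.10, 1.9080, 0.1094, 1.70),
    "OD1": (-0.80, 1.6612, 0.2100, 1.50),
    "OE1": (-0.60, 1.6612, 0.2100, 1.50),
    "OG1": (-0.50, 1.7210, 0.2104, 1.52),
    "NE": (0.80, 1.8240, 0.1700, 1.55),
    "NZ": (0.60, 1.8240, 0.1700, 1.55),
    "NE1": (-0.30, 1.8240, 0.1700, 1.55),
    "CD1": (-0.05, 1.9080, 0.1094, 1.70),
}
_LIGAND_CHARGES = [0.20, -0.20, 0.10, -0.10, 0.00]


@dataclass
class SyntheticSpec:
    """Full recipe for one stochastic ensemble."""

    reference: StructureModel
    residue_corr: np.ndarray  # R x R, over residues in order of appearance
    per_residue_sigma: float | np.ndarray = 0.5  # Angstrom
    n_frames: int = 1000
    seed: int = 0
    rigid_jitter: tuple[float, float] = (1.0, 5.0)  # (max translation A, max rotation deg)


@dataclass
class PlantedTruth:
    """Ground truth actually used to sample an ensemble."""

    residue_ids: list[tuple[str, int]]  # (chain, resid) per correlation-matrix row
    community_labels: dict[int, int]  # receptor resid -> block label (-1 background)
    chain_residues: list[int] = field(default_factory=list)
    source: int | None = None
    target: int | None = None
    corr_planted: np.ndarray | None = None  # matrix actually sampled from (post repair)
    repair_max_delta: float = 0.0
    seed: int = 0


def _helix_point(i: int, radius: float) -> np.ndarray:
    ang = np.deg2rad(_TWIST_DEG * i)
    return np.array([radius * np.cos(ang), radius * np.sin(ang), _RISE * i])


def build_toy_complex(
    n_receptor_residues: int,
    include_ligand: bool = True,
    include_peptide: bool = True,
    start_resid: int = 575,
) -> tuple[StructureModel, pd.DataFrame]:
    """Deterministic toy receptor(+ligand+peptide) with per-atom parameters.

    The receptor is a helix-like C-alpha trace (chain A) with one side-chain
    pseudo-atom per residue; the optional ligand is a 5-atom group (chain L,
    resname LIG) inside the helix pocket; the optional peptide (chain P,
    sequence L-R-A-L-L, resids 1-5) docks its arginine NE against the OD1 of
    the aspartate-like receptor residue it is anchored to, giving the
    energetics and hydrogen-bond stages a charged contact with ground truth.
    Returns the structure and a parameter table (charge, LJ, Born radius).
    """
    n = int(n_receptor_residues)
    if n < 6:
        raise StructureError("toy receptor needs at least 6 residues")
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n):
        resid = start_resid + i
        resname, side_name = _SPECIAL_RESIDUES.get(resid, ("ALA", "CB"))
        ca = _helix_point(i, _CA_RADIUS)
        side = _helix_point(i, _SIDE_RADIUS)
        atoms.append(AtomRecord(serial, "CA", resname, resid, "A", "C", tuple(ca)))
        serial += 1
        elem = side_name[0]
        atoms.append(AtomRecord(serial, side_name, resname, resid, "A", elem, tuple(side)))
        serial += 1

    if include_ligand:
        # small cross of atoms on the helix axis, mid-height: the "pocket"
        zc = _RISE * (n - 1) / 2.0
        offsets = np.array(
            [[0, 0, 0], [1.2, 0, 0], [-1.2, 0, 0], [0, 1.2, 0], [0, 0, 1.2]], float
        )
        for j, off in enumerate(offsets):
            pos = np.array([0.0, 0.0, zc]) + off
            atoms.append(AtomRecord(serial, f"C{j + 1}", "LIG", 900, "L", "C", tuple(pos)))
            serial += 1

    if include_peptide:
        # anchor the peptide near residue 590 if present, else mid-helix
        anchor = 590 if start_resid <= 590 < start_resid + n else start_resid + n // 2
        i_anchor = anchor - start_resid
        ang = np.deg2rad(_TWIST_DEG * i_anchor)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])  # outward radial direction
        z0 = _RISE * i_anchor
        pep = [("LEU", "CD1"), ("ARG", "NE"), ("ALA", "CB"), ("LEU", "CD1"), ("LEU", "CD1")]
        for j, (resname, side_name) in enumerate(pep):
            z = z0 + (j - 1) * 3.5  # residue 2 (the arginine) level with the anchor
            ca = u * 8.0 + np.array([0.0, 0.0, z])
            # arginine NE reaches toward the anchor OD1 (at radius 3.8): ~2.8 A gap
            side_r = 6.6 if side_name == "NE" else 9.0
            side = u * side_r + np.array([0.0, 0.0, z])
            atoms.append(AtomRecord(serial, "CA", resname, j + 1, "P", "C", tuple(ca)))
            serial += 1
            atoms.append(
                AtomRecord(serial, side_name, resname, j + 1, "P", side_name[0], tuple(side))
            )
            serial += 1

    structure = StructureModel(atoms, title=f"toy complex n={n}")
    rows = []
    lig_counter = 0
    for a in structure.atoms:
        if a.residue_name == "LIG":
            q = _LIGAND_CHARGES[lig_counter % len(_LIGAND_CHARGES)]
            lig_counter += 1
            rmin2, eps, born = 1.9080, 0.1094, 1.70
        else:
            q, rmin2, eps, born = _ATOM_PARAMS.get(a.name, (0.0, 1.9080, 0.1094, 1.70))
        rows.append(
            {
                "serial": a.serial,
                "charge_e": q,
                "lj_rmin_half_A": rmin2,
                "lj_eps_kcal_mol": eps,
                "born_radius_A": born,
            }
        )
    return structure, pd.DataFrame(rows)


def residues_of(structure: StructureModel) -> list[tuple[str, int]]:
    """Ordered unique (chain, resid) pairs, in order of appearance."""
    seen: list[tuple[str, int]] = []
    for a in structure.atoms:
        key = (a.chain_id, a.residue_id)
        if not seen or seen[-1] != key:
            if key in seen:
                raise StructureError(f"residue {key} not contiguous in atom order")
            seen.append(key)
    return seen


def _psd_repair(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues to 0 and rescale the diagonal back to 1."""
    w, V = np.linalg.eigh(matrix)
    if w.min() >= -1e-12:
        return matrix, 0.0
    w_clipped = np.clip(w, 0.0, None)
    repaired = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.abs(repaired - matrix).max())


def plant_correlation(
    n_residues: int,
    blocks: Sequence[tuple[Sequence[int], float]] = (),
    chain: tuple[Sequence[int], float] | None = None,
    background: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Build a residue-level target correlation matrix with planted structure.

    ``blocks`` is a list of (residue index set, intra-block rho): each block
    is a future network community.  ``chain`` is (ordered index list, link
    rho): consecutive chain members get the link correlation, encoding a
    ground-truth allosteric path.  Everything else gets ``background``.  The
    result is symmetrised and repaired to positive semidefinite by eigenvalue
    clipping; the report states how far the repair moved any entry.
    """
    r = int(n_residues)
    for rho in [background] + [b[1] for b in blocks] + ([chain[1]] if chain else []):
        if not (0.0 <= abs(rho) < 1.0):
            raise AnalysisError(f"off-diagonal correlation {rho} outside [0, 1)")
    seen: set[int] = set()
    for idx, _ in blocks:
        s = set(int(i) for i in idx)
        if s & seen:
            raise AnalysisError("planted blocks overlap")
        if not s <= set(range(r)):
            raise AnalysisError("block index out of range")
        seen |= s
    C = np.full((r, r), float(background))
    np.fill_diagonal(C, 1.0)
    for idx, rho in blocks:
        ii = np.asarray(sorted(int(i) for i in idx))
        C[np.ix_(ii, ii)] = rho
        C[ii, ii] = 1.0
    if chain is not None:
        order, rho = chain
        order = [int(i) for i in order]
        for a, b in zip(order[:-1], order[1:]):
            C[a, b] = C[b, a] = rho
    C = (C + C.T) / 2.0
    repaired, delta = _psd_repair(C)
    report = {"repaired": delta > 0.0, "max_delta": delta}
    return repaired, report


def sample_ensemble(spec: SyntheticSpec, truth: PlantedTruth | None = None) -> tuple[Ensemble, PlantedTruth]:
    """Draw an ensemble whose residue-level DCCM converges to the planted matrix.

    Per frame, one displacement per residue is drawn from N(0, sigma^2 * C)
    independently on each Cartesian axis and applied to *all* atoms of that
    residue; the frame is then rigid-jittered.  Fully reproducible for a
    fixed seed (single numpy Generator stream).
    """
    if spec.n_frames < 2:
        raise AnalysisError("need at least 2 frames")
    residues = residues_of(spec.reference)
    r = len(residues)
    C = np.asarray(spec.residue_corr, float)
    if C.shape != (r, r):
        raise AnalysisError(f"residue_corr shape {C.shape} != ({r}, {r})")
    if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise AnalysisError("residue_corr must be symmetric with unit diagonal")
    C, delta = _psd_repair(C)

    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    sigma = np.broadcast_to(np.asarray(spec.per_residue_sigma, float), (r,))

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, r, 3))
    disp = np.einsum("ij,fja->fia", L, z) * sigma[None, :, None]

    res_index = {key: k for k, key in enumerate(residues)}
    atom_res = np.array(
        [res_index[(a.chain_id, a.residue_id)] for a in spec.reference.atoms], int
    )
    ref = spec.reference.coordinates
    frames = ref[None, :, :] + disp[:, atom_res, :]

    max_t, max_deg = spec.rigid_jitter
    if max_t > 0 or max_deg > 0:
        center = ref.mean(axis=0)
        for f in range(spec.n_frames):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
            R = Rotation.from_rotvec(axis * angle).as_matrix()
            t = rng.uniform(-max_t, max_t, size=3)
            frames[f] = (frames[f] - center) @ R.T + center + t

    if truth is None:
        truth = PlantedTruth(
            residue_ids=residues,
            community_labels={rid: -1 for ch, rid in residues if ch == "A"},
        )
    truth.residue_ids = residues
    truth.corr_planted = C
    truth.repair_max_delta = max(truth.repair_max_delta, delta)
    truth.seed = spec.seed
    ensemble = Ensemble(frames, spec.reference)
    return ensemble, truth


def write_fixture(
    ensemble: Ensemble,
    truth: PlantedTruth,
    params: pd.DataFrame,
    out_dir: str | Path,
    reference: StructureModel | None = None,
) -> dict[str, Path]:
    """Write ensemble (multi-model PDB), parameter TSV and truth manifest (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "ensemble": out / "ensemble.pdb",
        "reference": out / "reference.pdb",
        "params": out / "params.tsv",
        "truth": out / "truth.json",
    }
    write_ensemble(ensemble, files["ensemble"])
    write_structure(reference if reference is not None else ensemble.topology, files["reference"])
    params.to_csv(files["params"], sep="\t", index=False)
    manifest = {
        "seed": truth.seed,
        "n_frames": ensemble.n_frames,
        "residue_ids": [[ch, rid] for ch, rid in truth.residue_ids],
        "community_labels": {str(k): int(v) for k, v in truth.community_labels.items()},
        "chain_residues": [int(x) for x in truth.chain_residues],
        "source": truth.source,
        "target": truth.target,
        "repair_max_delta": truth.repair_max_delta,
        "corr_planted": np.round(truth.corr_planted, 6).tolist()
        if truth.corr_planted is not None
        else None,
    }
    files["truth"].write_text(json.dumps(manifest, indent=1))
    return files


def read_fixture(fixture_dir: str | Path) -> tuple[Ensemble, PlantedTruth, pd.DataFrame]:
    """Read back a fixture written by :func:`write_fixture`."""
    from .trajectory import read_ensemble

    d = Path(fixture_dir)
    ensemble = read_ensemble(d / "ensemble.pdb")
    params = pd.read_csv(d / "params.tsv", sep="\t")
    m = json.loads((d / "truth.json").read_text())
    truth = PlantedTruth(
        residue_ids=[(ch, int(rid)) for ch, rid in m["residue_ids"]],
        community_labels={int(k): int(v) for k, v in m["community_labels"].items()},
        chain_residues=[int(x) for x in m["chain_residues"]],
        source=m["source"],
        target=m["target"],
        corr_planted=np.asarray(m["corr_planted"], float) if m["corr_planted"] else None,
        repair_max_delta=float(m["repair_max_delta"]),
        seed=int(m["seed"]),
    )
    return ensemble, truth, params


# ---------------------------------------------------------------------------
# Preset study conditions


def _two_cluster_structure(cluster_size: int = 8) -> StructureModel:
    """Two compact residue clusters (one C-alpha per residue) joined by a
    narrow spatial bridge: the contact graph is two near-cliques plus a few
    bridge edges, the classic planted-community topology."""
    # cube vertices scaled to a 2.0 A circumsphere: every intra-cluster pair
    # sits within 4.0 A, so each cluster is a contact clique
    a = 2.0 / np.sqrt(3.0)
    cube = np.array(
        [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
         [-1, 1, 1], [1, 1, 1], [1, -1, 1], [-1, -1, 1]],
        float,
    ) * a
    atoms: list[AtomRecord] = []
    serial = 1
    for first_resid, offset in [(521, np.zeros(3)), (541, np.array([6.3, 0.0, 0.0]))]:
        for k in range(cluster_size):
            pos = cube[k % 8] + offset + np.array([0.0, 0.0, 4.0 * (k // 8)])
            atoms.append(AtomRecord(serial, "CA", "ALA", first_resid + k, "A", "C", tuple(pos)))
            serial += 1
    return StructureModel(atoms, title="two-cluster toy")


def community_study_spec(
    n_receptor_residues: int = 16,
    seed: int = 0,
    n_frames: int = 600,
    intra_rho: float = 0.8,
    sigma: float = 0.3,
) -> tuple[SyntheticSpec, PlantedTruth, pd.DataFrame]:
    """Two correlated, spatially compact blocks: ground truth for communities.

    The structure is two dense residue clusters bridged by a few contacts.
    Within each cluster the correlation decays with sequence separation as
    intra_rho**|i-j| (an AR(1) profile); across clusters it is zero.  The
    decaying profile keeps the planted signal in internal modes that survive
    rigid-body superposition: a flat equicorrelated block is mostly a
    block-translation mode, which the least-squares fit would absorb and
    redistribute.
    """
    cluster_size = max(4, n_receptor_residues // 2)
    structure = _two_cluster_structure(cluster_size)
    residues = residues_of(structure)
    block_a = list(range(cluster_size))
    block_b = list(range(cluster_size, 2 * cluster_size))
    corr = np.eye(len(residues))
    for block in (block_a, block_b):
        for a, i in enumerate(block):
            for b, j in enumerate(block):
                corr[i, j] = intra_rho ** abs(a - b)
    corr, delta = _psd_repair(corr)
    labels = {}
    for i in block_a:
        labels[residues[i][1]] = 0
    for i in block_b:
        labels[residues[i][1]] = 1
    params = pd.DataFrame(
        {
            "serial": [a.serial for a in structure.atoms],
            "charge_e": 0.0,
            "lj_rmin_half_A": 1.908,
            "lj_eps_kcal_mol": 0.1094,
            "born_radius_A": 1.7,
        }
    )
    truth = PlantedTruth(
        residue_ids=residues, community_labels=labels, repair_max_delta=delta
    )
    spec = SyntheticSpec(
        reference=structure,
        residue_corr=corr,
        per_residue_sigma=sigma,
        n_frames=n_frames,
        seed=seed,
    )
    return spec, truth, params


def path_study_spec(
    n_receptor_residues: int = 40,
    seed: int = 0,
    n_frames: int = 600,
    link_rho: float = 0.9,
    sigma: float = 0.5,
    start_resid: int = 575,
) -> tuple[SyntheticSpec, PlantedTruth, pd.DataFrame]:
    """A planted high-correlation residue chain: ground truth for path finding.

    The chain steps along the helix in (i, i+3) contacts from resid 602 down
    to resid 590 (the cofactor-pocket aspartate analogue), so consecutive
    chain members are both spatially adjacent and strongly correlated; all
    other pairs are uncorrelated.
    """
    structure, params = build_toy_complex(n_receptor_residues, start_resid=start_resid)
    residues = residues_of(structure)
    index = {rid: i for i, (ch, rid) in enumerate(residues) if ch == "A"}
    chain_resids = [602, 599, 596, 593, 590]
    if not all(r in index for r in chain_resids):
        raise AnalysisError("toy receptor too small for the default planted chain")
    chain_idx = [index[r] for r in chain_resids]
    corr, report = plant_correlation(len(residues), chain=(chain_idx, link_rho))
    truth = PlantedTruth(
        residue_ids=residues,
        community_labels={rid: -1 for ch, rid in residues if ch == "A"},
        chain_residues=chain_resids,
        source=chain_resids[0],
        target=chain_resids[-1],
        repair_max_delta=report["max_delta"],
    )
    spec = SyntheticSpec(
        reference=structure,
        residue_corr=corr,
        per_residue_sigma=sigma,
        n_frames=n_frames,
        seed=seed,
    )
    return spec, truth, params
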