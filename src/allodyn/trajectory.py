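"""Structure and ensemble I/O, atom selections, superposition, RMSD and RMSF.

Coordinates are in Angstrom throughout and residue numbering is PDB author
numbering (no internal renumbering), so residues can be addressed exactly as
they are written in the literature (e.g. D590, T739 of the glucocorticoid
receptor ligand-binding domain).

File parsing and the selection language are delegated to MDAnalysis; this
module wraps them in light-weight, numpy-backed containers so every
downstream analysis works on plain ``(frames, atoms, 3)`` arrays.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, SelectionError, StructureError

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "MotifMapping",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "resolve_selection",
    "superpose",
    "kabsch",
    "rmsd_series",
    "rmsf_profile",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus reference position (Angstrom)."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    position: tuple[float, float, float]


@dataclass
class StructureModel:
    """An ordered list of atoms forming a single structural model."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure contains no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serial numbers in structure")
        if not np.isfinite(self.coordinates).all():
            raise StructureError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(A, 3) float array of positions."""
        return np.asarray([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray, title: str | None = None) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(f"coordinate shape {coords.shape} != ({self.n_atoms}, 3)")
        atoms = [
            AtomRecord(a.serial, a.name, a.residue_name, a.residue_id, a.chain_id, a.element, tuple(xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, self.title if title is None else title)

    def atom_index(self, chain_id: str, residue_id: int, name: str) -> int:
        """Index of the unique atom addressed by (chain, residue id, atom name)."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_id == residue_id and a.name == name
        ]
        if len(hits) != 1:
            raise SelectionError(
                f"atom {chain_id}:{residue_id}:{name} resolves to {len(hits)} atoms (need exactly 1)"
            )
        return hits[0]


@dataclass
class Ensemble:
    """A conformational ensemble: (F, A, 3) coordinates over a fixed topology."""

    frames: np.ndarray
    topology: StructureModel
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError(f"frames must be (F, A, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise StructureError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.frames).all():
            raise StructureError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, index: int, title: str | None = None) -> StructureModel:
        """Extract one frame as a full-topology StructureModel."""
        return self.topology.with_coordinates(
            self.frames[index], title if title is not None else f"frame {index}"
        )


@dataclass
class MotifMapping:
    """Relative cofactor-motif labels resolved to concrete residues.

    Anchored at the first leucine (L+1) of an LXXLL-style motif, as used for
    nuclear-receptor coactivator peptides: labels ``L+1``..``L+5`` address the
    motif residues, and ``R+2`` addresses the arginine at motif position +2.
    """

    labels: Mapping[str, tuple[str, int]] = field(default_factory=dict)

    @classmethod
    def from_anchor(cls, topology: StructureModel, chain_id: str, anchor_residue_id: int) -> "MotifMapping":
        present = {(a.chain_id, a.residue_id) for a in topology.atoms}
        labels: dict[str, tuple[str, int]] = {}
        for offset in range(5):
            rid = anchor_residue_id + offset
            if (chain_id, rid) not in present:
                raise SelectionError(f"motif residue {chain_id}:{rid} (L+{offset + 1}) absent from topology")
            labels[f"L+{offset + 1}"] = (chain_id, rid)
        labels["R+2"] = (chain_id, anchor_residue_id + 1)
        return cls(labels)

    def resolve(self, label: str) -> tuple[str, int]:
        if label not in self.labels:
            raise SelectionError(f"unknown motif label {label!r}; known: {sorted(self.labels)}")
        return self.labels[label]


# ---------------------------------------------------------------------------
# MDAnalysis bridge


def _universe_from_topology(topology: StructureModel) -> mda.Universe:
    """Build a one-frame MDAnalysis universe mirroring a StructureModel."""
    atoms = topology.atoms
    residue_keys: list[tuple[str, int, str]] = []
    atom_resindex = []
    for a in atoms:
        key = (a.chain_id, a.residue_id, a.residue_name)
        if not residue_keys or residue_keys[-1] != key:
            residue_keys.append(key)
        atom_resindex.append(len(residue_keys) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            len(atoms),
            n_residues=len(residue_keys),
            atom_resindex=atom_resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in atoms])
        u.add_TopologyAttr("ids", [a.serial for a in atoms])
        u.add_TopologyAttr("elements", [a.element for a in atoms])
        u.add_TopologyAttr("resids", [k[1] for k in residue_keys])
        u.add_TopologyAttr("resnames", [k[2] for k in residue_keys])
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in atoms])
        u.atoms.positions = topology.coordinates
    return u


def _structure_from_universe(u: mda.Universe, title: str = "") -> StructureModel:
    ag = u.atoms
    try:
        icodes = ag.icodes
    except (AttributeError, mda.exceptions.NoDataError):
        icodes = [""] * len(ag)
    if any(str(ic).strip() for ic in icodes):
        raise StructureError("insertion codes are not supported")
    try:
        altlocs = [str(a).strip() for a in ag.altLocs]
    except (AttributeError, mda.exceptions.NoDataError):
        altlocs = [""] * len(ag)
    keep = [i for i, al in enumerate(altlocs) if al in ("", "A")]
    ag = ag[keep]
    if len(ag) == 0:
        raise StructureError("no atoms after altloc filtering")

    def _attr(name: str, default: str) -> list[str]:
        try:
            return [str(v) for v in getattr(ag, name)]
        except (AttributeError, mda.exceptions.NoDataError):
            return [default] * len(ag)

    names = _attr("names", "X")
    elements = _attr("elements", "")
    chains = _attr("chainIDs", "A")
    try:
        serials = [int(s) for s in ag.ids]
    except (AttributeError, mda.exceptions.NoDataError):
        serials = list(range(1, len(ag) + 1))
    records = [
        AtomRecord(
            serial=serials[i],
            name=names[i],
            residue_name=str(ag.resnames[i]),
            residue_id=int(ag.resids[i]),
            chain_id=chains[i] if chains[i].strip() else "A",
            element=elements[i],
            position=tuple(float(x) for x in ag.positions[i]),
        )
        for i in range(len(ag))
    ]
    return StructureModel(records, title=title)


def read_structure(path: str | Path, fmt: str = "pdb") -> StructureModel:
    """Read a single-model structure from a PDB file."""
    path = Path(path)
    if fmt.lower() != "pdb":
        raise StructureError(f"unsupported structure format {fmt!r}")
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, IndexError, EOFError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise StructureError(f"{path} contains no ATOM/HETATM records")
    return _structure_from_universe(u, title=path.stem)


def read_ensemble(
    path: str | Path,
    topology_path: str | Path | None = None,
    frame_interval: float | None = None,
) -> Ensemble:
    """Read a conformational ensemble.

    ``path`` is a multi-model PDB, or a DCD trajectory if ``topology_path``
    (a PDB) is also given.  All models must share atom count and order.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology_path is not None:
                u = mda.Universe(str(topology_path), str(path))
            else:
                u = mda.Universe(str(path))
            if u.atoms.n_atoms == 0:
                raise StructureError(f"{path} contains no atoms")
            frames = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    except StructureError:
        raise
    except (ValueError, IndexError, EOFError) as exc:
        raise StructureError(f"inconsistent or unreadable ensemble {path}: {exc}") from exc
    topo = _structure_from_universe(u, title=path.stem)
    if topo.n_atoms != frames.shape[1]:  # altloc filtering applied
        keep = [a.serial for a in topo.atoms]
        serial_to_col = {int(s): i for i, s in enumerate(u.atoms.ids)}
        frames = frames[:, [serial_to_col[s] for s in keep], :]
    return Ensemble(frames=frames, topology=topo, frame_interval=frame_interval)


def _format_pdb_atom(a: AtomRecord, xyz: Sequence[float]) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    record = "HETATM" if a.residue_name in ("LIG",) else "ATOM  "
    return (
        f"{record}{a.serial:>5d} {name:<4s}{a.residue_name:>4s} "
        f"{a.chain_id:1s}{a.residue_id:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB."""
    lines = [f"TITLE     {structure.title}"] if structure.title else []
    lines += [_format_pdb_atom(a, a.position) for a in structure.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL blocks), the canonical fixture format."""
    lines: list[str] = []
    if ensemble.topology.title:
        lines.append(f"TITLE     {ensemble.topology.title}")
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        lines += [
            _format_pdb_atom(a, xyz)
            for a, xyz in zip(ensemble.topology.atoms, ensemble.frames[f])
        ]
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_CHAIN_WORD = re.compile(r"\bchain\b")


def resolve_selection(target: Ensemble | StructureModel, expression: str) -> np.ndarray:
    """Resolve a selection expression to an ordered (file-order) index array.

    Uses the MDAnalysis selection language (``"name CA"``,
    ``"chainID A and resid 521-777 and name CA"``...); the shorthand ``chain``
    is accepted as an alias for ``chainID``.  Raises SelectionError when the
    expression is invalid or matches nothing.
    """
    topo = target.topology if isinstance(target, Ensemble) else target
    u = _universe_from_topology(topo)
    expr = _CHAIN_WORD.sub("chainID", expression)
    try:
        ag = u.select_atoms(expr)
    except Exception as exc:  # MDAnalysis raises assorted SelectionErrors
        raise SelectionError(f"invalid selection {expression!r}: {exc}") from exc
    if len(ag) == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return np.sort(ag.indices.astype(int))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising ||mobile @ R.T + t - reference||.

    Mass-unweighted least squares; the determinant of R is forced to +1 so the
    fit can never mirror the structure.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise AnalysisError("superposition needs >= 3 paired atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if s[1] < 1e-10:  # rank < 2: atoms collinear, rotation underdetermined
        raise AnalysisError("fit atoms are (nearly) collinear; superposition is ill-posed")
    t = rc - R @ mc
    return R, t


def superpose(ensemble: Ensemble, reference: StructureModel, fit_selection: str) -> Ensemble:
    """Rigidly fit every frame onto the reference over ``fit_selection`` (Kabsch).

    Atoms outside the fit selection are carried along by the same transform.
    """
    idx_e = resolve_selection(ensemble, fit_selection)
    idx_r = resolve_selection(reference, fit_selection)
    if len(idx_e) != len(idx_r):
        raise SelectionError(
            f"fit selection resolves to {len(idx_e)} ensemble atoms but {len(idx_r)} reference atoms"
        )
    ref_xyz = reference.coordinates[idx_r]
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        R, t = kabsch(ensemble.frames[f][idx_e], ref_xyz)
        out[f] = ensemble.frames[f] @ R.T + t
    return Ensemble(out, ensemble.topology, ensemble.frame_interval)


def rmsd_series(
    ensemble: Ensemble, reference: StructureModel, selection: str = "name CA"
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) of the selection relative to the reference.

    Computed on the coordinates as given; superpose first for fitted RMSD.
    """
    idx_e = resolve_selection(ensemble, selection)
    idx_r = resolve_selection(reference, selection)
    if len(idx_e) != len(idx_r):
        raise SelectionError("selection resolves differently in ensemble and reference")
    diff = ensemble.frames[:, idx_e, :] - reference.coordinates[idx_r]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def rmsf_profile(ensemble: Ensemble, selection: str = "name CA") -> np.ndarray:
    """Per-atom RMSF (Angstrom) about the time-mean position, over the selection."""
    if ensemble.n_frames < 2:
        raise AnalysisError("RMSF undefined for fewer than 2 frames")
    idx = resolve_selection(ensemble, selection)
    xyz = ensemble.frames[:, idx, :]
    dev = xyz - xyz.mean(axis=0, keepdims=True)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))
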