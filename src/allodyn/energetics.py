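"""End-point interaction-energy decomposition (MM/GBSA style).

Single-trajectory binding free energy between two atom groups sharing the
same frames:

    dG_binding = dE_MM + dG_solv            (the entropic -TS term is omitted)
    dE_MM      = dE_vdw + dE_ele + dE_int   (dE_int == 0 in single-trajectory mode:
                                             intramolecular bonded terms cancel)
    dG_solv    = dE_polar + dE_nonpolar

The polar solvation term uses a pairwise Generalized Born model with fixed,
user-supplied Born radii; the nonpolar term is the linear SASA model
dE_nonpolar = gamma * SASA + b applied per species and combined as
complex - receptor - partner.  Defaults: gamma = 0.00542 kcal/mol/A^2,
b = 0.92 kcal/mol, interior/solvent dielectrics 1/80, probe 1.4 A.

Per-residue attribution follows the half-and-half convention: each cross-pair
energy is split equally between the two residues it connects, so rows over
both species sum exactly to the totals; the constant offset b (owned by no
residue) is spread equally across rows to keep that identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .trajectory import Ensemble, StructureModel, resolve_selection

__all__ = [
    "KE_KCAL_A_MOL_E2",
    "ForceFieldParameters",
    "EnergyDecomposition",
    "lj_energy",
    "coulomb_energy",
    "gb_energy",
    "gb_polar",
    "sasa",
    "sphere_points",
    "nonpolar_solvation",
    "binding_total",
    "binding_decomposition",
]

KE_KCAL_A_MOL_E2 = 332.0637  # Coulomb constant, kcal*A/(mol*e^2)
_OVERLAP_R = 0.1  # Angstrom; closer pairs indicate a broken geometry


@dataclass
class ForceFieldParameters:
    """Per-atom nonbonded parameters plus global solvation constants.

    Per-atom arrays are aligned with topology atom order (one row per atom):
    partial charge (e), LJ Rmin/2 (A), LJ well depth epsilon (kcal/mol) and
    Born radius (A).
    """

    charge: np.ndarray
    lj_rmin_half: np.ndarray
    lj_eps: np.ndarray
    born_radius: np.ndarray
    serial: np.ndarray = field(default_factory=lambda: np.array([], int))
    eps_interior: float = 1.0
    eps_solvent: float = 80.0
    gamma: float = 0.00542  # kcal/mol/A^2
    b_offset: float = 0.92  # kcal/mol
    probe_radius: float = 1.4  # A

    def __post_init__(self) -> None:
        for name in ("charge", "lj_rmin_half", "lj_eps", "born_radius"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if (self.lj_eps < 0).any():
            raise AnalysisError("negative LJ epsilon")
        if (self.lj_rmin_half <= 0).any() or (self.born_radius <= 0).any():
            raise AnalysisError("non-positive radius parameter")

    @classmethod
    def from_table(cls, table: pd.DataFrame, topology: StructureModel, **globals_) -> "ForceFieldParameters":
        """Align a parameter TSV table (keyed by serial) with a topology."""
        by_serial = table.set_index("serial")
        serials = [a.serial for a in topology.atoms]
        missing = [s for s in serials if s not in by_serial.index]
        if missing:
            raise AnalysisError(f"parameters missing for serials {missing[:5]}...")
        sub = by_serial.loc[serials]
        return cls(
            charge=sub["charge_e"].to_numpy(),
            lj_rmin_half=sub["lj_rmin_half_A"].to_numpy(),
            lj_eps=sub["lj_eps_kcal_mol"].to_numpy(),
            born_radius=sub["born_radius_A"].to_numpy(),
            serial=np.asarray(serials, int),
            **globals_,
        )


def _cross_distances(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                     params: ForceFieldParameters | None = None) -> np.ndarray:
    r = np.linalg.norm(coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=2)
    if (r < _OVERLAP_R).any():
        i, j = np.argwhere(r < _OVERLAP_R)[0]
        sa = params.serial[idx_a[i]] if params is not None and params.serial.size else idx_a[i]
        sb = params.serial[idx_b[j]] if params is not None and params.serial.size else idx_b[j]
        raise AnalysisError(f"atoms {sa} and {sb} overlap (r < {_OVERLAP_R} A)")
    return r


def _lj_matrix(coords, idx_a, idx_b, params) -> np.ndarray:
    r = _cross_distances(coords, idx_a, idx_b, params)
    rmin = params.lj_rmin_half[idx_a][:, None] + params.lj_rmin_half[idx_b][None, :]
    eps = np.sqrt(params.lj_eps[idx_a][:, None] * params.lj_eps[idx_b][None, :])
    x6 = (rmin / r) ** 6
    return eps * (x6 * x6 - 2.0 * x6)


def _coulomb_matrix(coords, idx_a, idx_b, params) -> np.ndarray:
    r = _cross_distances(coords, idx_a, idx_b, params)
    qq = params.charge[idx_a][:, None] * params.charge[idx_b][None, :]
    return KE_KCAL_A_MOL_E2 * qq / (params.eps_interior * r)


def _fgb(r: np.ndarray, a_i: np.ndarray, a_j: np.ndarray) -> np.ndarray:
    aa = a_i[:, None] * a_j[None, :]
    return np.sqrt(r * r + aa * np.exp(-(r * r) / (4.0 * aa)))


def _gb_prefactor(params: ForceFieldParameters) -> float:
    return -KE_KCAL_A_MOL_E2 * (1.0 / params.eps_interior - 1.0 / params.eps_solvent)


def _gb_cross_matrix(coords, idx_a, idx_b, params) -> np.ndarray:
    r = np.linalg.norm(coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=2)
    f = _fgb(r, params.born_radius[idx_a], params.born_radius[idx_b])
    qq = params.charge[idx_a][:, None] * params.charge[idx_b][None, :]
    return _gb_prefactor(params) * qq / f


def lj_energy(coords: np.ndarray, idx_a, idx_b, params: ForceFieldParameters) -> float:
    """Lennard-Jones cross energy between two disjoint groups, kcal/mol.

    eps_ij [(Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6] with Lorentz-Berthelot combining
    (Rmin_ij = Rmin_i/2 + Rmin_j/2, eps_ij = sqrt(eps_i eps_j)); no cutoff.
    """
    idx_a, idx_b = _check_groups(idx_a, idx_b)
    return float(_lj_matrix(np.asarray(coords, float), idx_a, idx_b, params).sum())


def coulomb_energy(coords: np.ndarray, idx_a, idx_b, params: ForceFieldParameters) -> float:
    """Coulomb cross energy k_e q_i q_j / (eps_in r), kcal/mol."""
    idx_a, idx_b = _check_groups(idx_a, idx_b)
    return float(_coulomb_matrix(np.asarray(coords, float), idx_a, idx_b, params).sum())


def gb_energy(coords: np.ndarray, idx, params: ForceFieldParameters) -> float:
    """Generalized Born polar solvation self-energy of one group, kcal/mol.

    -1/2 k_e (1/eps_in - 1/eps_solv) sum_ij q_i q_j / f_GB over all pairs
    including i == j (f_GB(0) = a_i gives the Born self term -.. q^2 / (2 a)).
    """
    idx = np.asarray(idx, int)
    coords = np.asarray(coords, float)
    r = np.linalg.norm(coords[idx][:, None, :] - coords[idx][None, :, :], axis=2)
    f = _fgb(r, params.born_radius[idx], params.born_radius[idx])
    qq = params.charge[idx][:, None] * params.charge[idx][None, :]
    return float(0.5 * _gb_prefactor(params) * (qq / f).sum())


def gb_polar(coords: np.ndarray, idx_a, idx_b, params: ForceFieldParameters) -> float:
    """GB polar contribution to binding: E(complex) - E(A) - E(B) on one frame.

    With fixed Born radii this reduces to the cross-pair GB sum.  Exactly 0
    when interior and solvent dielectrics are equal.
    """
    idx_a, idx_b = _check_groups(idx_a, idx_b)
    return float(_gb_cross_matrix(np.asarray(coords, float), idx_a, idx_b, params).sum())


def _check_groups(idx_a, idx_b) -> tuple[np.ndarray, np.ndarray]:
    idx_a = np.asarray(idx_a, int)
    idx_b = np.asarray(idx_b, int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise AnalysisError("empty atom group")
    if np.intersect1d(idx_a, idx_b).size:
        raise AnalysisError("atom groups overlap")
    return idx_a, idx_b


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral construction)."""
    if n < 12:
        raise AnalysisError("need at least 12 sphere points")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2.

    Test points sit on a sphere of radius r_i + probe around each atom; a
    point is buried iff it lies strictly inside some neighbour's expanded
    sphere (distance < r_j + probe).  The strict inequality is the tie rule:
    exactly coincident identical atoms do not occlude each other.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.shape[0] != radii.shape[0]:
        raise AnalysisError("coords/radii length mismatch")
    unit = sphere_points(n_points)
    n = coords.shape[0]
    expanded = radii + probe
    out = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_points, bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) > expanded[i] + expanded[j]:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            # small slack keeps the strict radius test strict under rounding
            exposed &= ~(d2 < expanded[j] ** 2 - 1e-9)
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return out


def nonpolar_solvation(
    sasa_complex: float,
    sasa_a: float,
    sasa_b: float,
    gamma: float = 0.00542,
    b: float = 0.92,
) -> float:
    """Nonpolar solvation contribution to binding, kcal/mol.

    gamma*SASA + b evaluated per species, combined as complex - A - B
    (so the offsets contribute exactly -b).
    """
    term = lambda s: gamma * s + b
    return term(sasa_complex) - term(sasa_a) - term(sasa_b)


def binding_total(
    vdw: float, ele: float, nonpolar: float, polar: float, internal: float = 0.0
) -> float:
    """Aggregate component terms into the binding free energy.

    dG_binding = (dE_vdw + dE_ele + dE_int) + (dE_polar + dE_nonpolar); this
    is the same aggregation path used frame-by-frame in the decomposition.
    """
    return (vdw + ele + internal) + (polar + nonpolar)


@dataclass
class EnergyDecomposition:
    """Per-frame totals, their statistics, and the per-residue table.

    ``frames``: DataFrame indexed by frame with columns vdw, ele, internal,
    polar, nonpolar, solv, mm, binding (kcal/mol).  ``per_residue``: one row
    per residue of either species, mean and sd columns per term; rows sum to
    the corresponding total means within bookkeeping tolerance.
    """

    frames: pd.DataFrame
    per_residue: pd.DataFrame

    @property
    def mean(self) -> pd.Series:
        return self.frames.mean(axis=0)

    @property
    def sd(self) -> pd.Series:
        return self.frames.std(axis=0, ddof=1)

    def summary_table(self) -> pd.DataFrame:
        """Term rows x (mean, sd) columns, Tables-1/2 style."""
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


_TERMS = ("vdw", "ele", "polar", "nonpolar")


def binding_decomposition(
    ensemble: Ensemble,
    receptor_selection: str,
    partner_selection: str,
    params: ForceFieldParameters,
    stride: int = 1,
    n_sphere_points: int = 240,
) -> EnergyDecomposition:
    """Single-trajectory binding decomposition between two selections.

    Complex, receptor and partner geometries come from the same frames, so
    the internal (bonded) term cancels and is reported as exactly 0.  Every
    term is also attributed per residue (cross pairs half/half, SASA by own
    atoms, the b offset spread equally) so rows sum to totals exactly.
    """
    idx_r = resolve_selection(ensemble, receptor_selection)
    idx_p = resolve_selection(ensemble, partner_selection)
    idx_r, idx_p = _check_groups(idx_r, idx_p)
    frames = range(0, ensemble.n_frames, max(1, int(stride)))
    if len(frames) == 0:
        raise AnalysisError("no frames after stride")

    atoms = ensemble.topology.atoms
    res_of = {}
    residues: list[tuple[str, int]] = []
    for i in np.concatenate([idx_r, idx_p]):
        key = (atoms[i].chain_id, atoms[i].residue_id)
        if key not in res_of:
            res_of[key] = len(residues)
            residues.append(key)
        # map atom -> residue row
    atom_row = {int(i): res_of[(atoms[i].chain_id, atoms[i].residue_id)] for i in np.concatenate([idx_r, idx_p])}
    n_res = len(residues)

    totals = {t: [] for t in _TERMS}
    per_res = {t: [] for t in _TERMS}
    for f in frames:
        xyz = ensemble.frames[f]
        mats = {
            "vdw": _lj_matrix(xyz, idx_r, idx_p, params),
            "ele": _coulomb_matrix(xyz, idx_r, idx_p, params),
            "polar": _gb_cross_matrix(xyz, idx_r, idx_p, params),
        }
        idx_all = np.concatenate([idx_r, idx_p])
        s_complex = sasa(xyz[idx_all], params.born_radius[idx_all], params.probe_radius, n_sphere_points)
        s_r = sasa(xyz[idx_r], params.born_radius[idx_r], params.probe_radius, n_sphere_points)
        s_p = sasa(xyz[idx_p], params.born_radius[idx_p], params.probe_radius, n_sphere_points)
        d_sasa = s_complex - np.concatenate([s_r, s_p])  # per atom of complex
        np_total = params.gamma * d_sasa.sum() - params.b_offset

        rows = {t: np.zeros(n_res) for t in _TERMS}
        for t in ("vdw", "ele", "polar"):
            half_r = 0.5 * mats[t].sum(axis=1)
            half_p = 0.5 * mats[t].sum(axis=0)
            for a, v in zip(idx_r, half_r):
                rows[t][atom_row[int(a)]] += v
            for a, v in zip(idx_p, half_p):
                rows[t][atom_row[int(a)]] += v
            totals[t].append(float(mats[t].sum()))
        for a, dv in zip(idx_all, d_sasa):
            rows["nonpolar"][atom_row[int(a)]] += params.gamma * dv
        rows["nonpolar"] -= params.b_offset / n_res
        totals["nonpolar"].append(np_total)
        for t in _TERMS:
            per_res[t].append(rows[t])

    df = pd.DataFrame({t: totals[t] for t in _TERMS}, index=list(frames))
    df["internal"] = 0.0
    df["solv"] = df["polar"] + df["nonpolar"]
    df["mm"] = df["vdw"] + df["ele"] + df["internal"]
    df["binding"] = df["mm"] + df["solv"]

    res_index = [f"{ch}:{rid}" for ch, rid in residues]
    per = {}
    for t in _TERMS:
        arr = np.asarray(per_res[t])
        per[f"{t}_mean"] = arr.mean(axis=0)
        per[f"{t}_sd"] = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(n_res)
    per_df = pd.DataFrame(per, index=res_index)
    per_df["binding_mean"] = sum(per_df[f"{t}_mean"] for t in _TERMS)
    return EnergyDecomposition(frames=df, per_residue=per_df)
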