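"""Pocket geometry observables: distances, H-bond occupancy, triangle-area
collective variables and 2D free-energy landscapes.

The openness of a binding pocket is summarised by the area of the triangle
spanned by three marker residues (for the glucocorticoid receptor: the
cofactor pocket by D590-K579-E755, the ligand pocket by D638-D742-W557);
projecting the sampled probability density of two such collective variables
onto -kT ln P gives the 2D conformational free-energy landscape.  Hydrogen
bonds are scored by a plain donor-acceptor heavy-atom distance criterion
(formed iff d <= 3.5 A, no angle term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import AnalysisError, SelectionError
from .trajectory import Ensemble, MotifMapping

__all__ = [
    "KB_KCAL_MOL_K",
    "AtomRef",
    "TriangleCV",
    "LandscapeGrid",
    "distance_series",
    "distance_density",
    "hbond_occupancy",
    "triangle_area_series",
    "fel_2d",
]

KB_KCAL_MOL_K = 0.0019872  # Boltzmann constant, kcal/mol/K


@dataclass(frozen=True)
class AtomRef:
    """A single atom addressed by (chain, resid, name) or a motif label.

    Examples: ``AtomRef("A", 590, "OD1")``, ``AtomRef.parse("A:590:OD1")``,
    ``AtomRef.parse("R+2:NE")`` (resolved through a MotifMapping).
    """

    chain_id: str | None
    residue_id: int | None
    atom_name: str
    motif_label: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomRef":
        parts = text.strip().split(":")
        if len(parts) == 2:  # motif form "R+2:NE"
            return cls(None, None, parts[1], motif_label=parts[0])
        if len(parts) == 3:
            return cls(parts[0], int(parts[1]), parts[2])
        raise SelectionError(f"cannot parse atom reference {text!r}")

    def resolve(self, ensemble: Ensemble, motif: MotifMapping | None = None) -> int:
        if self.motif_label is not None:
            if motif is None:
                raise SelectionError(f"motif label {self.motif_label!r} needs a MotifMapping")
            chain, resid = motif.resolve(self.motif_label)
        else:
            chain, resid = self.chain_id, self.residue_id
        return ensemble.topology.atom_index(chain, resid, self.atom_name)

    def __str__(self) -> str:
        if self.motif_label is not None:
            return f"{self.motif_label}:{self.atom_name}"
        return f"{self.chain_id}:{self.residue_id}:{self.atom_name}"


@dataclass(frozen=True)
class TriangleCV:
    """Area collective variable over three distinct atoms."""

    a: AtomRef
    b: AtomRef
    c: AtomRef
    name: str = ""

    def refs(self) -> tuple[AtomRef, AtomRef, AtomRef]:
        return (self.a, self.b, self.c)


@dataclass
class LandscapeGrid:
    """2D free-energy landscape: counts and -kT ln(P/Pmax) on a CV grid."""

    cv1_edges: np.ndarray
    cv2_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ma.MaskedArray  # kcal/mol, min 0 on occupied bins; empty bins masked
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return ~self.free_energy.mask


def distance_series(
    ensemble: Ensemble, a: AtomRef | str, b: AtomRef | str, motif: MotifMapping | None = None
) -> np.ndarray:
    """Per-frame Euclidean distance (Angstrom) between two atoms."""
    a = AtomRef.parse(a) if isinstance(a, str) else a
    b = AtomRef.parse(b) if isinstance(b, str) else b
    ia, ib = a.resolve(ensemble, motif), b.resolve(ensemble, motif)
    if ia == ib:
        raise SelectionError("distance between an atom and itself")
    return np.linalg.norm(ensemble.frames[:, ia, :] - ensemble.frames[:, ib, :], axis=1)


def distance_density(
    series: np.ndarray,
    bins: int | str = "fd",
    kde: bool = False,
    bandwidth: float | str = "silverman",
) -> tuple[np.ndarray, np.ndarray]:
    """Density estimate over a distance series; integrates to 1 over its support.

    Histogram with Freedman-Diaconis bins by default; Gaussian KDE (Silverman
    bandwidth unless given) on request.  A degenerate all-identical series
    with KDE falls back to a delta-like histogram with a warning.
    Returns (grid centers, density values).
    """
    x = np.asarray(series, float)
    if x.size < 2:
        raise AnalysisError("need at least 2 samples for a density")
    if kde:
        if np.ptp(x) == 0.0:
            warnings.warn("all samples identical; KDE undefined, returning delta-like histogram")
        else:
            k = gaussian_kde(x, bw_method=bandwidth)
            grid = np.linspace(x.min() - 3 * k.factor * x.std(), x.max() + 3 * k.factor * x.std(), 512)
            return grid, k(grid)
    counts, edges = np.histogram(x, bins=bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts


def hbond_occupancy(series: np.ndarray, cutoff: float = 3.5) -> float:
    """Fraction of frames with distance <= cutoff (inclusive boundary).

    The default 3.5 A is the heavy-atom distance beyond which a hydrogen
    bond is considered unable to form.
    """
    x = np.asarray(series, float)
    if x.size == 0:
        raise AnalysisError("empty distance series")
    return float(np.mean(x <= cutoff))


def triangle_area_series(
    ensemble: Ensemble, cv: TriangleCV, motif: MotifMapping | None = None
) -> np.ndarray:
    """Per-frame triangle area (Angstrom^2) of the CV's three atoms."""
    ia, ib, ic = (ref.resolve(ensemble, motif) for ref in cv.refs())
    if len({ia, ib, ic}) != 3:
        raise SelectionError(f"triangle CV {cv.name!r} atoms are not distinct")
    p = ensemble.frames
    u = p[:, ib, :] - p[:, ia, :]
    v = p[:, ic, :] - p[:, ia, :]
    return 0.5 * np.linalg.norm(np.cross(u, v), axis=1)


def fel_2d(
    cv1: np.ndarray,
    cv2: np.ndarray,
    bins: int | tuple[int, int] = 50,
    temperature: float = 300.0,
    pad_fraction: float = 0.05,
) -> LandscapeGrid:
    """2D free-energy landscape F = -kT ln(P/Pmax) from two CV series.

    Bins default to 50x50 over the observed range padded by 5%; the global
    minimum is shifted to 0 and empty bins are masked (never -kT ln 0).
    """
    x = np.asarray(cv1, float)
    y = np.asarray(cv2, float)
    if x.shape != y.shape:
        raise AnalysisError("CV series lengths differ")
    if isinstance(bins, int):
        bins = (bins, bins)

    def _edges(v: np.ndarray, n: int) -> np.ndarray:
        lo, hi = v.min(), v.max()
        pad = 0.5 if hi == lo else (hi - lo) * pad_fraction
        return np.linspace(lo - pad, hi + pad, n + 1)

    ex, ey = _edges(x, bins[0]), _edges(y, bins[1])
    counts, _, _ = np.histogram2d(x, y, bins=(ex, ey))
    kt = KB_KCAL_MOL_K * temperature
    with np.errstate(divide="ignore"):
        fe = -kt * np.log(counts / counts.max())
    fe = np.ma.masked_array(fe, mask=counts == 0)
    return LandscapeGrid(ex, ey, counts, fe, float(temperature))
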