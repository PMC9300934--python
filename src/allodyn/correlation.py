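"""Covariance and dynamic cross-correlation matrices (DCCM).

Over a superposed ensemble, for selected atoms i and j with position vectors
r_i(t), the scalar covariance is

    c_ij = <r_i . r_j> - <r_i> . <r_j>        (Angstrom^2)

and the cross-correlation is C_ij = c_ij / sqrt(c_ii c_jj), in [-1, 1].
Nodes are conventionally the C-alpha atoms, one per residue, so C_ij reads
directly as residue-residue correlated motion; it later supplies the
-log|C_ij| edge weights of the allosteric network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError
from .trajectory import Ensemble, resolve_selection

__all__ = [
    "CovarianceMatrix",
    "CorrelationMatrix",
    "covariance",
    "dccm",
    "dccm_multi",
    "dccm_difference",
]


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray  # R x R, Angstrom^2
    residue_ids: list[tuple[str, int]]  # (chain, resid) per row
    selection: str = ""


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray  # R x R in [-1, 1]; NaN rows/cols where variance is 0
    residue_ids: list[tuple[str, int]]
    selection: str = ""

    def masked(self) -> np.ndarray:
        return np.ma.masked_invalid(self.matrix)


def _selected_labels(ensemble: Ensemble, idx: np.ndarray) -> list[tuple[str, int]]:
    return [
        (ensemble.topology.atoms[i].chain_id, ensemble.topology.atoms[i].residue_id)
        for i in idx
    ]


def covariance(ensemble: Ensemble, selection: str = "name CA") -> CovarianceMatrix:
    """Scalar (dot-product) position covariance over the selection.

    The ensemble must already be superposed; covariance of raw frames mixes
    rigid-body motion into every entry.
    """
    if ensemble.n_frames < 2:
        raise AnalysisError("covariance needs at least 2 frames")
    idx = resolve_selection(ensemble, selection)
    x = ensemble.frames[:, idx, :]  # (F, R, 3)
    dx = x - x.mean(axis=0, keepdims=True)
    c = np.einsum("fia,fja->ij", dx, dx) / x.shape[0]
    c = (c + c.T) / 2.0
    return CovarianceMatrix(c, _selected_labels(ensemble, idx), selection)


def dccm(ensemble: Ensemble, selection: str = "name CA") -> CorrelationMatrix:
    """Dynamic cross-correlation matrix C_ij = c_ij / sqrt(c_ii c_jj).

    Zero-variance atoms produce a masked (NaN) row/column with a warning,
    never a silent 0.  Entries are clamped to [-1, 1] against floating-point
    overflow only.
    """
    cov = covariance(ensemble, selection)
    d = np.diag(cov.matrix).copy()
    dead = d <= 1e-12
    if dead.any():
        labels = [cov.residue_ids[i] for i in np.nonzero(dead)[0]]
        warnings.warn(f"zero-variance nodes masked in DCCM: {labels}")
    with np.errstate(divide="ignore", invalid="ignore"):
        C = cov.matrix / np.sqrt(np.outer(d, d))
    if np.nanmax(np.abs(C)) > 1.0 + 1e-12:
        raise AnalysisError("correlation overflow beyond floating tolerance")
    C = np.clip(C, -1.0, 1.0)
    C[dead, :] = np.nan
    C[:, dead] = np.nan
    return CorrelationMatrix(C, cov.residue_ids, selection)


def dccm_multi(
    ensembles: Sequence[Ensemble], selection: str = "name CA", mode: str = "average"
) -> CorrelationMatrix:
    """DCCM over replicas: elementwise average of per-replica DCCMs (default),
    or one DCCM of the concatenated frames (``mode='pooled'``)."""
    if not ensembles:
        raise AnalysisError("no ensembles given")
    if mode == "pooled":
        frames = np.concatenate([e.frames for e in ensembles], axis=0)
        pooled = Ensemble(frames, ensembles[0].topology)
        return dccm(pooled, selection)
    if mode != "average":
        raise AnalysisError(f"unknown replica mode {mode!r}")
    mats = [dccm(e, selection) for e in ensembles]
    for m in mats[1:]:
        if m.residue_ids != mats[0].residue_ids:
            raise AnalysisError("replica selections resolve to different residues")
    avg = np.mean([m.matrix for m in mats], axis=0)
    return CorrelationMatrix(avg, mats[0].residue_ids, selection)


def dccm_difference(a: CorrelationMatrix, b: CorrelationMatrix) -> np.ndarray:
    """Elementwise a - b difference map (for cross-system comparison)."""
    if a.residue_ids != b.residue_ids:
        raise AnalysisError("correlation matrices cover different residues")
    return a.matrix - b.matrix
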