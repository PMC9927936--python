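"""Rigid-body superposition and PCA of helix-segment conformations.

Frames are first least-squares superposed (Kabsch) onto a reference over a
fit set of atoms — typically all Cα of the TM bundle — so that global
rotation/translation is removed before any conformational statistics.  PCA
is then run on the flattened 3N coordinates of an analysis selection (for
receptor activation work, the Cα of the extracellular halves of TM2, TM6
and TM7), and multiple ensembles (apo / Na+-bound / agonist-bound) can be
projected into the one component space fitted on any of them.

Numerical conventions: covariance uses the unbiased (n−1) denominator;
eigenvector sign is pinned so the first nonzero coordinate of each
component is positive, making projections reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .bw import BWTable
from .structure_io import AtomIndexSet, Frame, Trajectory, select_atoms

__all__ = [
    "PCAModel",
    "superpose",
    "rmsd",
    "fit_pca",
    "project",
    "extracellular_half_selection",
]


@dataclass
class PCAModel:
    """Principal components of flattened (3N) coordinates of a selection."""

    atom_set: AtomIndexSet
    mean_coords: np.ndarray  # (3N,)
    components: np.ndarray  # (n_components, 3N), orthonormal rows
    eigenvalues: np.ndarray  # variances (Å²), descending

    def __post_init__(self):
        self.mean_coords = np.asarray(self.mean_coords, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        k, d = self.components.shape
        if self.mean_coords.shape != (d,) or self.eigenvalues.shape != (k,):
            raise ValueError("inconsistent PCA model shapes")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("components are not orthonormal")
        if np.any(self.eigenvalues < -1e-10) or np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-negative and descending")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _kabsch_transform(ref: np.ndarray, mov: np.ndarray):
    """Rotation and centroids minimising RMSD of mov onto ref."""
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    return rot, ref_c, mov_c


def superpose(traj: Trajectory, reference: Frame, fit_set: AtomIndexSet) -> Trajectory:
    """Rigid-body fit of every frame onto the reference over ``fit_set``.

    Each frame is rotated/translated to minimise the RMSD of the fit atoms
    to the reference coordinates (Kabsch least squares).  The whole frame is
    transformed, not only the fit atoms.
    """
    idx = fit_set.as_array()
    if idx.size < 3:
        raise ValueError("fit set needs at least 3 atoms")
    ref = reference.coordinates[idx]
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit set is collinear or degenerate in the reference")

    out = np.empty_like(traj.coords)
    for t in range(traj.n_frames):
        mov = traj.coords[t, idx]
        rot, ref_c, mov_c = _kabsch_transform(ref, mov)
        out[t] = rot.apply(traj.coords[t] - mov_c) + ref_c
    return traj.with_coords(out, source_label=traj.source_label + " (superposed)")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of two matched coordinate sets (Å)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _pin_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for i, v in enumerate(out):
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            out[i] = -v
    return out


def fit_pca(aligned: Trajectory, atom_set: AtomIndexSet) -> PCAModel:
    """Eigendecomposition of the coordinate covariance of a selection.

    Input frames must already be superposed consistently; PCA itself does
    no fitting.  All 3N components are returned in descending-variance
    order (at most ``n_frames − 1`` of them carry nonzero variance).
    """
    if aligned.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = atom_set.as_array()
    if idx.size == 0:
        raise ValueError("empty atom selection")
    X = aligned.coords[:, idx, :].reshape(aligned.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (aligned.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    components = _pin_signs(evecs[:, order].T)
    return PCAModel(
        atom_set=atom_set, mean_coords=mean, components=components, eigenvalues=evals
    )


def project(model: PCAModel, traj: Trajectory, component_ids: list[int] | None = None) -> np.ndarray:
    """Per-frame coordinates along selected components (Å).

    ``component_ids`` are 0-based; ``None`` projects onto all components.
    The projected trajectory may be a different ensemble than the one the
    model was fitted on, provided it was superposed consistently.
    """
    idx = model.atom_set.as_array()
    X = traj.coords[:, idx, :].reshape(traj.n_frames, -1)
    if X.shape[1] != model.mean_coords.size:
        raise ValueError("trajectory selection does not match the PCA model")
    if component_ids is None:
        comp = model.components
    else:
        for c in component_ids:
            if not 0 <= c < model.n_components:
                raise ValueError(f"component id {c} out of range")
        comp = model.components[list(component_ids)]
    return (X - model.mean_coords) @ comp.T


def extracellular_half_selection(
    table: BWTable,
    traj: Trajectory,
    helices: list[int] | tuple[int, ...] = (2, 6, 7),
    chain: str | None = None,
) -> AtomIndexSet:
    """Cα atoms of the extracellular half of each named helix.

    The default cut is the helix-range midpoint (by residue index); a
    per-helix ``half_cuts`` entry in the table overrides it with the last
    cytoplasmic residue, making the halves complementary to a published
    cytoplasmic-segment definition.  The extracellular end of each helix is
    identified from the table's per-helix direction flag.
    """
    residues: list[int] = []
    for h in helices:
        if h not in table.helix_ranges:
            raise ValueError(f"helix {h} missing from table")
        lo, hi = table.helix_ranges[h]
        ec_cterm = table.extracellular_is_cterm.get(h, h % 2 == 0)
        if h in table.half_cuts:
            cut = table.half_cuts[h]
            ec_range = range(cut + 1, hi + 1) if ec_cterm else range(lo, cut)
        else:
            mid = (lo + hi) // 2
            ec_range = range(mid, hi + 1) if ec_cterm else range(lo, mid + 1)
        residues.extend(ec_range)
    if not residues:
        return AtomIndexSet(())
    return select_atoms(traj, chain=chain, residue_id=residues, atom_name="CA")
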