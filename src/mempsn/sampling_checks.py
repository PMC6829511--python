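"""Essential-dynamics sampling-homogeneity checks.

Frames are least-squares superposed onto a reference to remove rigid-body
motion, the covariance matrix of the Cα positional fluctuations is
diagonalised, and the leading S eigenvectors (default S = 20) span the
essential subspace.  Replica consistency is quantified by the root-mean-square
inner product of two essential subspaces,

    RMSIP = sqrt( (1/S) Σ_ij (v_i^A · v_j^B)² ),

which is 1 for identical subspaces and 0 for mutually orthogonal ones, and by
the overlap of per-frame projections onto PC1/PC2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Topology, Trajectory


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose one coordinate set onto a reference
    (translation + proper rotation, equal weights)."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mob_c @ rot + reference.mean(axis=0)


@dataclass
class EssentialSubspace:
    eigenvectors: np.ndarray   # (3n, S), columns orthonormal
    eigenvalues: np.ndarray    # (S,), Ų, descending
    mean: np.ndarray           # (3n,) mean fitted coordinates
    selection: np.ndarray      # atom indices used
    reference: np.ndarray      # (n, 3) fitting reference
    superposed: bool = True

    @property
    def dimension(self) -> int:
        return self.eigenvectors.shape[1]


def calpha_selection(topology: Topology) -> np.ndarray:
    """Cα atoms of protein residues (falls back to one atom per protein
    residue for coarse bead models without CA names)."""
    sel = topology.select_atoms(molecule_class="protein", atom_names="CA")
    if len(sel):
        return sel
    return np.array(
        [r.atom_indices[0] for r in topology.protein_residues], dtype=int
    )


def _fitted_coordinates(trajectory: Trajectory, selection: np.ndarray,
                        reference: np.ndarray,
                        superpose: bool = True) -> np.ndarray:
    if not superpose:
        return trajectory.coords[:, selection, :].reshape(
            trajectory.n_frames, -1
        )
    fitted = np.empty((trajectory.n_frames, len(selection), 3))
    for f in range(trajectory.n_frames):
        fitted[f] = kabsch_superpose(
            trajectory.coords[f][selection], reference
        )
    return fitted.reshape(trajectory.n_frames, -1)


def essential_subspace(
    trajectory: Trajectory,
    topology: Topology | None = None,
    selection: np.ndarray | None = None,
    subspace_dim: int = 20,
    reference_frame: int = 0,
    superpose: bool = True,
) -> EssentialSubspace:
    """Top-S eigenpairs of the positional covariance of the fitted selection.

    ``superpose=False`` skips the rigid-body fit (useful when frames are
    already aligned, or for analytic fixtures whose motion must not be
    redistributed into rigid modes).
    """
    if selection is None:
        if topology is None:
            raise ValueError("supply a topology or an explicit selection")
        selection = calpha_selection(topology)
    selection = np.asarray(selection, dtype=int)
    n_dof = 3 * len(selection)
    subspace_dim = min(subspace_dim, n_dof)
    if trajectory.n_frames < subspace_dim:
        raise ValueError(
            f"need at least {subspace_dim} frames for an "
            f"{subspace_dim}-dimensional essential subspace, "
            f"got {trajectory.n_frames}"
        )
    reference = trajectory.coords[reference_frame][selection]
    x = _fitted_coordinates(trajectory, selection, reference, superpose)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (len(x) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:subspace_dim]
    return EssentialSubspace(
        eigenvectors=evecs[:, order],
        eigenvalues=np.clip(evals[order], 0.0, None),
        mean=mean, selection=selection, reference=reference,
        superposed=superpose,
    )


def rmsip(es_a: EssentialSubspace | np.ndarray,
          es_b: EssentialSubspace | np.ndarray) -> float:
    """Root-mean-square inner product of two essential subspaces."""
    va = es_a.eigenvectors if isinstance(es_a, EssentialSubspace) else es_a
    vb = es_b.eigenvectors if isinstance(es_b, EssentialSubspace) else es_b
    if va.shape != vb.shape:
        raise ValueError(
            f"subspace shapes differ: {va.shape} vs {vb.shape}"
        )
    overlaps = va.T @ vb
    s = va.shape[1]
    return float(np.sqrt(np.sum(overlaps ** 2) / s))


@dataclass
class PCProjection:
    pc1: np.ndarray   # (n_frames,) Å
    pc2: np.ndarray

    def bounding_box(self):
        return (self.pc1.min(), self.pc1.max(),
                self.pc2.min(), self.pc2.max())


def project(trajectory: Trajectory, es: EssentialSubspace) -> PCProjection:
    """Per-frame projections onto the leading two essential modes."""
    x = _fitted_coordinates(trajectory, es.selection, es.reference,
                            es.superposed)
    if x.shape[1] != len(es.mean):
        raise ValueError("trajectory selection does not match the subspace")
    xc = x - es.mean
    return PCProjection(xc @ es.eigenvectors[:, 0],
                        xc @ es.eigenvectors[:, 1])


def overlap_fraction(proj_a: PCProjection, proj_b: PCProjection) -> float:
    """Bounding-box intersection-over-union of two PC1/PC2 scatter clouds —
    a coarse, reported-only homogeneity measure."""
    ax0, ax1, ay0, ay1 = proj_a.bounding_box()
    bx0, bx1, by0, by1 = proj_b.bounding_box()
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = ((ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter)
    return float(inter / union) if union > 0 else 0.0
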