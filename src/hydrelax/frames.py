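"""Principal axis system (PAS) of the solute inertia tensor.

The motional environment of hydration water around an elongated solute is
assumed uniaxial; the symmetry axis z′ is the eigenvector belonging to the
smallest eigenvalue of the solute's inertia tensor.  Per analysis block the
PAS comes from the eigendecomposition of the block-mean inertia tensor
(averaging tensors is well defined; averaging eigenvectors is not).  The x′
and y′ axes in the perpendicular plane are arbitrary up to right-handedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hydrelax.trajectory import Trajectory, unwrap_group

DEGENERACY_RTOL = 1e-3


@dataclass
class PasFrame:
    rotation: np.ndarray       # (3,3) lab -> PAS; rows are x', y', z' in lab coords
    symmetry_axis: np.ndarray  # z' in lab frame
    block_index: int
    eigenvalues: np.ndarray    # amu Å², ascending

    def __post_init__(self):
        R = self.rotation
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-10:
            raise ValueError("rotation matrix not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must be proper (det = +1)")

    @classmethod
    def identity(cls, block_index: int = 0) -> "PasFrame":
        return cls(np.eye(3), np.array([0.0, 0.0, 1.0]), block_index, np.zeros(3))


def inertia_tensor(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Inertia tensor (amu Å²) about the center of mass."""
    coordinates = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coordinates.shape[0] < 2:
        raise ValueError("inertia tensor requires at least two atoms")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    r = coordinates - (masses[:, None] * coordinates).sum(axis=0) / total
    r2 = np.einsum("ij,ij->i", r, r)
    return np.eye(3) * np.dot(masses, r2) - np.einsum("i,ij,ik->jk", masses, r, r)


def symmetry_axis(tensor: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the smallest inertia eigenvalue (the long axis)."""
    tensor = np.asarray(tensor, dtype=float)
    if np.max(np.abs(tensor - tensor.T)) > 1e-8 * max(1.0, np.max(np.abs(tensor))):
        raise ValueError("inertia tensor must be symmetric")
    w, v = np.linalg.eigh(tensor)
    scale = abs(w[-1]) if w[-1] != 0 else 1.0
    if (w[1] - w[0]) < DEGENERACY_RTOL * scale:
        warnings.warn(
            "smallest two inertia eigenvalues nearly degenerate; "
            "symmetry axis is ill-defined"
        )
    return v[:, 0]


def _pas_from_tensor(tensor: np.ndarray, block_index: int, prev_axis: np.ndarray | None) -> PasFrame:
    w, v = np.linalg.eigh(tensor)
    scale = abs(w[-1]) if w[-1] != 0 else 1.0
    if (w[1] - w[0]) < DEGENERACY_RTOL * scale:
        warnings.warn("nearly degenerate inertia eigenvalues in block "
                      f"{block_index}; symmetry axis ill-defined")
    z = v[:, 0]
    # sign convention: continuity with previous block, else positive lab +z
    ref = prev_axis if prev_axis is not None else np.array([0.0, 0.0, 1.0])
    if np.dot(z, ref) < 0:
        z = -z
    x = v[:, 1]
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    if np.linalg.det(R) < 0:  # cannot happen after the cross product, kept as guard
        R[0] = -R[0]
    return PasFrame(R, z, block_index, w)


def block_pas(
    trajectory: Trajectory,
    peptide_indices: np.ndarray,
    block_length: float = 100.0,
) -> list[PasFrame]:
    """One PAS per trajectory block of ``block_length`` ps.

    The solute is unwrapped (minimum image relative to its first atom) in every
    frame, the inertia tensor is averaged over the frames of the block and the
    PAS is the eigenframe of that mean tensor.  Eigenvector signs are chained
    so consecutive block axes have positive dot product.
    """
    peptide_indices = np.asarray(peptide_indices)
    if peptide_indices.size == 0:
        raise ValueError("empty peptide selection")
    masses = trajectory.topology.masses[peptide_indices]
    frames_per_block = max(1, int(round(block_length / trajectory.sampling_interval))) \
        if trajectory.n_frames > 1 else 1
    out: list[PasFrame] = []
    prev = None
    for b, start in enumerate(range(0, trajectory.n_frames, frames_per_block)):
        stop = min(start + frames_per_block, trajectory.n_frames)
        mean_tensor = np.zeros((3, 3))
        for i in range(start, stop):
            coords = unwrap_group(
                trajectory.coordinates[i][peptide_indices], trajectory.boxes[i]
            )
            mean_tensor += inertia_tensor(coords, masses)
        mean_tensor /= stop - start
        pas = _pas_from_tensor(mean_tensor, b, prev)
        prev = pas.symmetry_axis
        out.append(pas)
    return out


def to_pas(vector: np.ndarray, pas: PasFrame) -> np.ndarray:
    """Rotate lab-frame vector(s) into the PAS (norm preserving)."""
    return np.asarray(vector) @ pas.rotation.T
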