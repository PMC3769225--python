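"""Normal-mode analysis of elastic networks.

The stiffness (Hessian) matrix of a bead-spring network is assembled from
3x3 blocks -k * e e^T per spring (e the unit bond vector), diagonal blocks
closing each block row to zero. All beads carry unit mass, so eigenvalues
are in kcal mol^-1 A^-2 and frequencies are sqrt(eigenvalue) in the model's
natural units; only ratios and percentage changes of fluctuation amplitudes
are physically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .constants import R_KCAL
from .structure import ElasticNetwork

__all__ = [
    "StiffnessMatrix",
    "ModeSpectrum",
    "FlexibilityProfile",
    "hessian",
    "eigenmodes",
    "bfactor_profile",
    "mode_frequencies",
]

#: Number of rigid-body (zero) modes of a connected 3D network.
N_RIGID = 6


@dataclass(frozen=True)
class StiffnessMatrix:
    """Dense symmetric 3N x 3N stiffness matrix with its node labels."""

    matrix: np.ndarray
    labels: tuple
    coords: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ModeSpectrum:
    """Eigen-decomposition of a StiffnessMatrix.

    eigenvalues  : ascending, kcal mol^-1 A^-2 (unit masses)
    eigenvectors : orthonormal columns, parallel to eigenvalues
    n_zero       : rigid-body mode count (6 for a connected network)
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    labels: tuple

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-node mean-square fluctuation (A^2) and B-factor (A^2)."""

    msf: np.ndarray
    bfactor: np.ndarray
    temperature: float
    labels: tuple


def hessian(net: ElasticNetwork) -> StiffnessMatrix:
    """Assemble the 3N x 3N stiffness matrix of the network."""
    n = net.n_nodes
    H = np.zeros((3 * n, 3 * n))
    coords = net.coords
    for (i, j), k in net.springs.items():
        d = coords[j] - coords[i]
        r = np.linalg.norm(d)
        e = d / r
        block = -k * np.outer(e, e)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, sj] += block
        H[sj, si] += block
        H[si, si] -= block
        H[sj, sj] -= block
    return StiffnessMatrix(H, net.labels, coords.copy())


def expected_rigid_modes(coords: np.ndarray | None) -> int:
    """6 for a 3D point cloud, 5 when all nodes are collinear."""
    if coords is None or len(coords) < 2:
        return N_RIGID
    centered = np.asarray(coords, float) - np.mean(coords, axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-8)
    return 5 if rank <= 1 else N_RIGID


def eigenmodes(H: StiffnessMatrix, zero_tol: float = 1e-9) -> ModeSpectrum:
    """Full symmetric eigendecomposition with rigid-body mode classification.

    Exactly six eigenvalues (five for a collinear geometry) must fall below
    zero_tol relative to the largest eigenvalue; a different count indicates
    a disconnected or internally degenerate network and raises. The
    rigid-body modes are identified by count after checking the spectral
    gap, not by threshold alone.
    """
    M = H.matrix
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("stiffness matrix is not symmetric")
    vals, vecs = scipy.linalg.eigh(M)
    scale = max(abs(vals[-1]), 1.0)
    if vals[0] < -zero_tol * scale * 100:
        raise ValueError(f"stiffness matrix not PSD: min eigenvalue {vals[0]:.3g}")
    expected = expected_rigid_modes(H.coords)
    n_small = int(np.sum(np.abs(vals) < zero_tol * scale))
    if n_small != expected:
        raise ValueError(
            f"expected {expected} rigid-body modes, found {n_small} "
            "(network disconnected or internally degenerate?)"
        )
    if vals[expected] < 10 * zero_tol * scale:
        raise ValueError("no spectral gap above the rigid-body modes")
    return ModeSpectrum(vals, vecs, expected, H.labels)


def bfactor_profile(spec: ModeSpectrum, temperature: float = 300.0) -> FlexibilityProfile:
    """Mean-square fluctuation and B-factor per node from the nonzero modes.

    msf_i = kB*T * sum_m |v_{m,i}|^2 / lambda_m over the node's x,y,z
    components; B_i = (8 pi^2 / 3) * msf_i. With unit masses and spring
    constants in kcal mol^-1 A^-2, kB*T is R*T in kcal mol^-1.
    """
    kbt = R_KCAL * temperature
    lam = spec.nonzero_eigenvalues
    vec = spec.eigenvectors[:, spec.n_zero:]
    per_coord = (vec ** 2) / lam[None, :]
    msf = kbt * per_coord.sum(axis=1).reshape(-1, 3).sum(axis=1)
    b = (8.0 * np.pi ** 2 / 3.0) * msf
    return FlexibilityProfile(msf, b, temperature, spec.labels)


def mode_frequencies(spec: ModeSpectrum) -> np.ndarray:
    """sqrt(eigenvalue) for the nonzero modes, ascending (unit masses)."""
    lam = spec.nonzero_eigenvalues
    if lam.size == 0:
        raise ValueError("spectrum has no nonzero modes")
    return np.sqrt(lam)


def write_spectrum_csv(spec: ModeSpectrum, path) -> None:
    """Export (mode index, eigenvalue, frequency) for the nonzero modes."""
    freqs = mode_frequencies(spec)
    with open(path, "w") as fh:
        fh.write("mode,eigenvalue,frequency\n")
        for m, (lam, f) in enumerate(zip(spec.nonzero_eigenvalues, freqs), 1):
            fh.write(f"{m},{lam:.12g},{f:.12g}\n")


def write_bfactor_csv(profile: FlexibilityProfile, path) -> None:
    """Export (chain, residue, B) for the C-alpha nodes."""
    with open(path, "w") as fh:
        fh.write("chain,residue,bfactor\n")
        for lab, b in zip(profile.labels, profile.bfactor):
            if lab.kind == "calpha":
                fh.write(f"{lab.chain},{lab.resnum},{b:.8g}\n")
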