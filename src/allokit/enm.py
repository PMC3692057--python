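"""Calpha elastic network model and low-frequency normal modes.

The anisotropic network model (ANM) connects Calpha atoms within a cutoff
(default 12 A) by uniform harmonic springs (gamma = 1, arbitrary units).
Its Hessian is built from per-contact 3x3 blocks -gamma * rhat rhat^T;
the six zero-eigenvalue rigid-body modes of a connected three-dimensional
network are discarded and the next ``n_modes`` lowest-frequency eigenpairs
are returned.  An anisotropic (vector) model is required because the
binding-leverage energies downstream need per-residue displacement
directions, not just magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "DisconnectedNetworkError",
    "DegenerateGeometryError",
    "build_elastic_network",
    "compute_modes",
]

#: Relative eigenvalue threshold below which a mode counts as rigid-body.
ZERO_MODE_RTOL = 1e-8


class DisconnectedNetworkError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class ElasticNetwork:
    ca_coords: np.ndarray          # (N, 3)
    contacts: np.ndarray           # (M, 2) index pairs, i < j
    cutoff: float
    spring_gamma: float = 1.0

    @property
    def n_atoms(self) -> int:
        return len(self.ca_coords)


@dataclass
class ModeSet:
    eigenvalues: np.ndarray        # (K,), ascending, all > zero threshold
    eigenvectors: np.ndarray       # (3N, K), orthonormal columns
    n_zero: int                    # removed rigid-body modes

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode(self, idx: int) -> np.ndarray:
        """Displacement field of retained mode ``idx`` as an (N, 3) array."""
        return self.eigenvectors[:, idx].reshape(-1, 3)


def build_elastic_network(s: Structure, cutoff: float = 12.0,
                          spring_gamma: float = 1.0) -> ElasticNetwork:
    """Connect Calpha pairs within ``cutoff``; the network must be a single
    connected component (otherwise rigid-body modes are not well separated
    from internal motion)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = s.ca_coords()
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))] if pairs.size else pairs.reshape(0, 2)
    if pairs.size:
        adj = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = n
    if n_comp != 1:
        raise DisconnectedNetworkError(
            f"elastic network has {n_comp} components at cutoff {cutoff} A; "
            "increase the cutoff or restrict to a connected set of chains"
        )
    return ElasticNetwork(ca_coords=coords, contacts=pairs, cutoff=cutoff,
                          spring_gamma=spring_gamma)


def anm_hessian(net: ElasticNetwork) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian (symmetric positive semi-definite)."""
    n = net.n_atoms
    h = np.zeros((3 * n, 3 * n))
    for i, j in net.contacts:
        d = net.ca_coords[j] - net.ca_coords[i]
        dist2 = float(d @ d)
        block = -net.spring_gamma * np.outer(d, d) / dist2
        h[3*i:3*i+3, 3*j:3*j+3] += block
        h[3*j:3*j+3, 3*i:3*i+3] += block
        h[3*i:3*i+3, 3*i:3*i+3] -= block
        h[3*j:3*j+3, 3*j:3*j+3] -= block
    return h


def compute_modes(net: ElasticNetwork, n_modes: int = 10) -> ModeSet:
    """Lowest ``n_modes`` non-rigid eigenpairs of the ANM Hessian.

    Rigid-body modes are identified by eigenvalue below ``ZERO_MODE_RTOL``
    times the Gershgorin upper bound of the spectrum; a connected
    three-dimensional network has exactly six.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    n = net.n_atoms
    if 3 * n - 6 < n_modes:
        raise ValueError(f"structure too small for {n_modes} non-rigid modes")
    h = anm_hessian(net)
    scale = float(np.abs(h).sum(axis=1).max())  # Gershgorin bound >= lambda_max
    k = 6 + n_modes
    vals, vecs = linalg.eigh(h, subset_by_index=[0, k - 1])
    thr = ZERO_MODE_RTOL * scale
    n_zero = int((vals < thr).sum())
    if n_zero > 6:
        raise DegenerateGeometryError(
            f"{n_zero} near-zero modes found; the network is disconnected "
            "or the geometry is degenerate"
        )
    if n_zero < 6:
        raise DegenerateGeometryError(
            f"only {n_zero} near-zero modes found; rigid-body modes are not "
            "numerically separated"
        )
    vals, vecs = vals[n_zero:k], vecs[:, n_zero:k]
    if len(vals) < n_modes:  # pragma: no cover - guarded by size check above
        raise ValueError("not enough non-rigid modes")
    vals, vecs = vals[:n_modes], vecs[:, :n_modes]
    # deterministic sign: first component of noticeable magnitude positive
    for c in range(vecs.shape[1]):
        col = vecs[:, c]
        idx = np.argmax(np.abs(col) > 1e-6)
        if col[idx] < 0:
            vecs[:, c] = -col
    return ModeSet(eigenvalues=vals.copy(), eigenvectors=vecs.copy(), n_zero=n_zero)
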