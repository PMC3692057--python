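"""Randomized property surveys used by the validation script and tests."""

from __future__ import annotations

import numpy as np

from .coupling import coupling_matrix, normalize_coupling
from .enm import build_elastic_network, compute_modes
from .fixtures import make_random_cluster
from .structure import site_from_sphere

__all__ = ["coupling_bound_survey", "rigid_motion_fit",
           "intercluster_mode_correlation"]


def rigid_motion_fit(coords: np.ndarray, displacements: np.ndarray) -> np.ndarray:
    """Least-squares rigid motion (translation t, rotation omega) best
    matching a displacement field u_i ~ t + omega x (r_i - r_mean).

    Returns the 6-vector (t, omega)."""
    x = coords - coords.mean(axis=0)
    a = np.zeros((3 * len(x), 6))
    for k, r in enumerate(x):
        a[3*k:3*k+3, :3] = np.eye(3)
        a[3*k:3*k+3, 3:] = np.array([[0.0, r[2], -r[1]],
                                     [-r[2], 0.0, r[0]],
                                     [r[1], -r[0], 0.0]])
    coef, *_ = np.linalg.lstsq(a, displacements.ravel(), rcond=None)
    return coef


def intercluster_mode_correlation(s, mode_field: np.ndarray) -> float:
    """Cosine between the rigid motions of the two clusters of a hinge
    fixture under one mode; negative values mean the clusters move
    counter-directionally (hinge-like)."""
    ca = s.ca_coords()
    sl1 = slice(*s.metadata["cluster1"])
    sl2 = slice(*s.metadata["cluster2"])
    v1 = rigid_motion_fit(ca[sl1], mode_field[sl1])
    v2 = rigid_motion_fit(ca[sl2], mode_field[sl2])
    return float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))


def coupling_bound_survey(n_structures: int = 1000, base_seed: int = 1,
                          n_residues: int = 40, n_sites: int = 3,
                          n_modes: int = 10) -> dict:
    """Stress the [0, 1] bound of the normalized leverage coupling.

    Generates ``n_structures`` random globular clusters, places ``n_sites``
    random sphere sites on each, computes the ANM mode set and the
    normalized coupling matrix (background included), and tracks the
    extreme entries encountered.

    Returns a dict with the maximum entry over all matrices (diagonal
    included), the maximum off-diagonal entry, the minimum entry, and the
    number of matrices surveyed.
    """
    max_entry = -np.inf
    max_offdiag = -np.inf
    min_entry = np.inf
    for i in range(n_structures):
        seed = int((base_seed + i) % (2**31 - 1))
        s = make_random_cluster(n=n_residues, seed=seed)
        rng = np.random.default_rng(seed + 7)
        net = build_elastic_network(s, cutoff=12.0)
        modes = compute_modes(net, n_modes=n_modes)
        centers = rng.choice(len(s.residues), size=n_sites, replace=False)
        sites = [site_from_sphere(s, s.residues[c].key, radius=6.0,
                                  site_id=f"s{k}")
                 for k, c in enumerate(centers)]
        c = normalize_coupling(coupling_matrix(sites, s, modes)).values
        off = c[~np.eye(len(c), dtype=bool)]
        max_entry = max(max_entry, float(c.max()))
        min_entry = min(min_entry, float(c.min()))
        if off.size:
            max_offdiag = max(max_offdiag, float(off.max()))
    return {
        "n_structures": n_structures,
        "max_entry": max_entry,
        "max_offdiagonal": max_offdiag,
        "min_entry": min_entry,
    }
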