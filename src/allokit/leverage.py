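"""Binding leverage: spring selection, mode deformation energies and
coarse-grained Monte Carlo probe docking.

Binding leverage measures how strongly a ligand bound at a site would
resist the protein's intrinsic low-frequency motions.  Harmonic springs
(rest length d_ij, constant kappa) are placed between every pair of Calpha
atoms whose connecting segment passes within a shell (default 3.5 A) of
any ligand/probe atom.  For a normal mode u^mu the linearized change in
spring length is

    delta_d_ij = (u_i - u_j) . (r_i - r_j) / d_ij

and the deformation energy of the spring set is
DeltaU_mu = (kappa/2) * sum_ij delta_d_ij^2.  The binding leverage of a
site for a mode set A is L_A = sum_{mu in A} DeltaU_mu.  kappa is an
arbitrary scale, so all leverage values are relative (dimensionless).

Candidate sites are discovered by docking a peptide-like probe of 2-6
Calpha beads (3.8 A spacing) with simulated-annealing Monte Carlo; the
energy rewards burial and penalizes clashes, and ligands already present
in the structure are invisible to the probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .enm import ModeSet
from .structure import Site, Structure, site_from_pose

__all__ = [
    "SpringSet",
    "ProbePose",
    "LeverageResult",
    "select_springs",
    "mode_delta_u",
    "binding_leverage_score",
    "mc_dock_probe",
    "rank_candidate_sites",
    "per_residue_leverage",
]

#: Probe bead spacing, A (virtual Calpha-Calpha bond).
BEAD_SPACING = 3.8
#: Default shell around ligand atoms for spring selection, A.
SPRING_SHELL = 3.5


@dataclass
class SpringSet:
    pairs: np.ndarray          # (M, 2) Calpha index pairs, i < j
    rest_lengths: np.ndarray   # (M,) d_ij, A
    unit_vectors: np.ndarray   # (M, 3) (r_i - r_j) / d_ij
    kappa: float = 1.0
    source: str = ""

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ProbePose:
    beads: np.ndarray          # (n_beads, 3)
    energy: float
    run_id: int
    step: int

    def centroid(self) -> np.ndarray:
        return self.beads.mean(axis=0)


@dataclass
class LeverageResult:
    per_mode: np.ndarray       # DeltaU_mu for each mode of the set used
    mode_indices: list[int] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.per_mode.sum())


def _point_segment_distance(a: np.ndarray, b: np.ndarray,
                            points: np.ndarray) -> np.ndarray:
    """Min distance from each segment [a_k, b_k] to the nearest of ``points``.

    a, b: (M, 3) segment endpoints; points: (P, 3).  Returns (M,).
    """
    ab = b - a                                    # (M, 3)
    ap = points[None, :, :] - a[:, None, :]       # (M, P, 3)
    denom = (ab * ab).sum(axis=1)                 # (M,)
    t = np.einsum("mpd,md->mp", ap, ab) / denom[:, None]
    t = np.clip(t, 0.0, 1.0)
    closest = a[:, None, :] + t[..., None] * ab[:, None, :]
    d = np.linalg.norm(points[None, :, :] - closest, axis=2)
    return d.min(axis=1)


def select_springs(ca_coords: np.ndarray, probe_atoms: np.ndarray,
                   shell: float = SPRING_SHELL,
                   prefilter: bool | None = True,
                   kappa: float = 1.0, source: str = "") -> SpringSet:
    """Select Calpha pairs whose connecting segment passes within ``shell``
    of any probe atom.

    ``prefilter`` enables a conservative pair-level bound that discards
    pairs which provably cannot qualify: for any point x on the segment
    [A, B] and probe atom p, |p - x| >= (|p - A| + |p - B| - |AB|) / 2, so
    a pair is excluded only when min_i |p_i - A| + min_i |p_i - B| exceeds
    |AB| + 2 * shell.  The bound never changes the selected set (pass
    ``None``/``False`` to disable it, as the brute-force oracle tests do).
    """
    ca = np.asarray(ca_coords, dtype=float)
    probe = np.asarray(probe_atoms, dtype=float).reshape(-1, 3)
    if len(ca) < 2:
        raise ValueError("need at least two Calpha atoms")
    if probe.size == 0:
        raise ValueError("need at least one probe atom")
    if shell <= 0:
        raise ValueError("shell must be positive")

    gi, gj = np.triu_indices(len(ca), k=1)
    if prefilter:
        tree = cKDTree(probe)
        dmin, _ = tree.query(ca, k=1)
        length = np.linalg.norm(ca[gi] - ca[gj], axis=1)
        keep = dmin[gi] + dmin[gj] <= length + 2.0 * shell
        gi, gj = gi[keep], gj[keep]
    if len(gi) == 0:
        return _empty_springs(kappa, source)
    sel_pairs = []
    chunk = 200_000 // max(len(probe), 1) + 1
    for start in range(0, len(gi), chunk):
        si = gi[start:start + chunk]
        sj = gj[start:start + chunk]
        d = _point_segment_distance(ca[si], ca[sj], probe)
        keep = d <= shell
        sel_pairs.append(np.stack([si[keep], sj[keep]], axis=1))
    pairs = np.concatenate(sel_pairs, axis=0) if sel_pairs else np.empty((0, 2), int)
    if pairs.size == 0:
        return _empty_springs(kappa, source)
    diff = ca[pairs[:, 0]] - ca[pairs[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    return SpringSet(pairs=pairs.astype(int), rest_lengths=d,
                     unit_vectors=diff / d[:, None], kappa=kappa, source=source)


def _empty_springs(kappa: float, source: str) -> SpringSet:
    return SpringSet(pairs=np.empty((0, 2), dtype=int),
                     rest_lengths=np.empty(0), unit_vectors=np.empty((0, 3)),
                     kappa=kappa, source=source)


def mode_delta_u(springs: SpringSet, mode: np.ndarray) -> float:
    """Deformation energy DeltaU_mu of the spring set for one mode vector.

    ``mode`` is the 3N eigenvector (or any displacement field flattened to
    3N); the result is (kappa/2) * sum of squared linearized length changes.
    """
    u = np.asarray(mode, dtype=float).reshape(-1, 3)
    if len(springs) == 0:
        return 0.0
    if springs.pairs.max() >= len(u):
        raise ValueError("mode dimension does not match the spring indices")
    rel = u[springs.pairs[:, 0]] - u[springs.pairs[:, 1]]
    dd = np.einsum("md,md->m", rel, springs.unit_vectors)
    return float(0.5 * springs.kappa * (dd ** 2).sum())


def binding_leverage_score(springs: SpringSet, modes: ModeSet,
                           mode_subset: list[int] | None = None) -> LeverageResult:
    """Binding leverage L_A = sum over the mode set of DeltaU_mu."""
    if mode_subset is None:
        mode_subset = list(range(modes.n_modes))
    if len(mode_subset) == 0:
        raise ValueError("mode subset must be non-empty")
    per = np.array([mode_delta_u(springs, modes.eigenvectors[:, m])
                    for m in mode_subset])
    return LeverageResult(per_mode=per, mode_indices=list(mode_subset))


# ---------------------------------------------------------------------------
# Monte Carlo probe docking


def _probe_energy(tree: cKDTree, beads: np.ndarray,
                  clash_radius: float, burial_radius: float,
                  clash_penalty: float) -> float:
    """Burial reward minus soft-core clash penalty, summed over beads:
    -1 per protein heavy atom in (clash_radius, burial_radius], plus
    +clash_penalty per atom within clash_radius."""
    c_out = tree.query_ball_point(beads, burial_radius, return_length=True).sum()
    c_in = tree.query_ball_point(beads, clash_radius, return_length=True).sum()
    return float(-(c_out - c_in) + clash_penalty * c_in)


def _initial_chain(rng: np.random.Generator, center: np.ndarray,
                   radius: float, n_beads: int) -> np.ndarray:
    """Random placement of a planar zigzag chain (120 deg virtual bond
    angles, like a Calpha trace).  A perfectly straight chain would make
    every torsion axis pass through all beads, freezing the internal
    degree of freedom."""
    local = np.zeros((n_beads, 3))
    step_x = BEAD_SPACING * math.cos(math.pi / 6.0)
    step_y = BEAD_SPACING * math.sin(math.pi / 6.0)
    for k in range(1, n_beads):
        local[k] = local[k - 1] + np.array([step_x, step_y if k % 2 else -step_y, 0.0])
    local -= local.mean(axis=0)
    rot = Rotation.random(rng=rng)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return center + radius * u + rot.apply(local)


def mc_dock_probe(s: Structure, probe_size: int = 4, n_runs: int = 10,
                  n_steps: int = 10_000, seed: int = 0, *,
                  translation_sigma: float = 0.5,
                  max_rotation_deg: float = 10.0,
                  max_torsion_deg: float = 20.0,
                  t_start: float = 2.0, t_end: float = 0.2,
                  clash_radius: float = 4.5, burial_radius: float = 7.5,
                  clash_penalty: float = 10.0) -> list[ProbePose]:
    """Dock a 2-6 bead peptide probe with simulated-annealing Monte Carlo.

    Each run starts from a random point on a sphere enclosing the protein;
    moves are rigid translations (Gaussian, sigma 0.5 A), rigid rotations
    (<= 10 deg) and single random torsion perturbations; the temperature
    anneals linearly from ``t_start`` to ``t_end``.  The lowest-energy pose
    of each run is returned.  Ligand atoms present in the structure are
    excluded from the energy (neither reward nor clash).  Identical
    (seed, inputs) yield identical poses.
    """
    if not 2 <= probe_size <= 6:
        raise ValueError(
            f"probe_size must be between 2 and 6 Calpha beads, got {probe_size}")
    if n_runs < 1 or n_steps < 1:
        raise ValueError("n_runs and n_steps must be >= 1")
    atoms, _ = s.heavy_atom_table()
    tree = cKDTree(atoms)
    center = atoms.mean(axis=0)
    enclose = float(np.linalg.norm(atoms - center, axis=1).max()) + 4.0

    def energy(beads: np.ndarray) -> float:
        return _probe_energy(tree, beads, clash_radius, burial_radius,
                             clash_penalty)

    poses: list[ProbePose] = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        beads = _initial_chain(rng, center, enclose, probe_size)
        e = energy(beads)
        best_beads, best_e, best_step = beads.copy(), e, 0
        n_move_kinds = 3 if probe_size >= 3 else 2
        for step in range(n_steps):
            t = t_start + (t_end - t_start) * step / max(n_steps - 1, 1)
            kind = rng.integers(n_move_kinds)
            if kind == 0:
                new = beads + rng.normal(0.0, translation_sigma, size=3)
            elif kind == 1:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = rng.uniform(-1.0, 1.0) * math.radians(max_rotation_deg)
                rot = Rotation.from_rotvec(axis * ang)
                c = beads.mean(axis=0)
                new = c + rot.apply(beads - c)
            else:
                j = int(rng.integers(probe_size - 2))
                axis = beads[j + 1] - beads[j]
                axis = axis / np.linalg.norm(axis)
                ang = rng.uniform(-1.0, 1.0) * math.radians(max_torsion_deg)
                rot = Rotation.from_rotvec(axis * ang)
                new = beads.copy()
                new[j + 2:] = beads[j + 1] + rot.apply(beads[j + 2:] - beads[j + 1])
            e_new = energy(new)
            de = e_new - e
            if de <= 0 or rng.random() < math.exp(-de / t):
                beads, e = new, e_new
                if e < best_e:
                    best_beads, best_e, best_step = beads.copy(), e, step
        poses.append(ProbePose(beads=best_beads, energy=best_e,
                               run_id=run, step=best_step))
    return poses


def cluster_poses(poses: list[ProbePose],
                  cluster_radius: float = 5.0) -> list[list[ProbePose]]:
    """Greedy clustering by bead-centroid distance; clusters are seeded in
    order of increasing energy, so each cluster's first member is its
    lowest-energy representative."""
    clusters: list[list[ProbePose]] = []
    for pose in sorted(poses, key=lambda p: (p.energy, p.run_id)):
        for cl in clusters:
            if np.linalg.norm(pose.centroid() - cl[0].centroid()) < cluster_radius:
                cl.append(pose)
                break
        else:
            clusters.append([pose])
    return clusters


def rank_candidate_sites(s: Structure, poses: list[ProbePose], modes: ModeSet,
                         cluster_radius: float = 5.0,
                         site_cutoff: float = 4.5,
                         shell: float = SPRING_SHELL
                         ) -> list[tuple[Site, LeverageResult]]:
    """Cluster docked poses, turn each cluster representative into a site,
    and rank the sites by total binding leverage (descending)."""
    if not poses:
        raise ValueError("need at least one probe pose")
    ca = s.ca_coords()
    ranked = []
    for idx, cl in enumerate(cluster_poses(poses, cluster_radius)):
        rep = cl[0]
        site = site_from_pose(s, rep.beads, site_id=f"dock{idx}",
                              cutoff=site_cutoff)
        if not site.residue_keys:
            continue  # pose never reached the structure
        springs = select_springs(ca, rep.beads, shell=shell,
                                 source=site.site_id)
        ranked.append((site, binding_leverage_score(springs, modes)))
    ranked.sort(key=lambda t: -t[1].total)
    return ranked


def per_residue_leverage(s: Structure, poses: list[ProbePose], modes: ModeSet,
                         site_cutoff: float = 4.5,
                         shell: float = SPRING_SHELL) -> dict:
    """Per-residue map: the maximum total leverage over all poses whose
    induced site contains the residue (0 for residues in no site)."""
    values = {r.key: 0.0 for r in s.residues}
    ca = s.ca_coords()
    for pose in poses:
        site = site_from_pose(s, pose.beads, site_id=f"pose{pose.run_id}",
                              cutoff=site_cutoff)
        springs = select_springs(ca, pose.beads, shell=shell)
        total = binding_leverage_score(springs, modes).total
        for key in site.residue_keys:
            if total > values[key]:
                values[key] = total
    return values
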