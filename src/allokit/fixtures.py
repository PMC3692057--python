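"""Deterministic synthetic protein structures for testing and validation.

All generators build poly-alanine chains (N, CA, C, O, CB per residue,
with periodic glycines exercising the Calpha fallback of the pseudo-ligand
rule) from a Calpha path laid out on jittered cubic lattices with ~3.8 A
neighbor spacing.  The geometry is intentionally simple — no Ramachandran
statistics, no packing optimization — but it is sufficient to give every
algorithm realistic inputs: residues form van der Waals contacts, elastic
networks are connected, and the hinge/pocket shapes produce the collective
motions and cavities the analysis is designed to detect.

Available shapes:

* ``make_hinge_dimer`` — two compact clusters joined by a thin linker; its
  softest internal mode is a hinge motion that moves the clusters against
  each other.
* ``make_pocket_cluster`` — a globular cluster with a concave cavity deep
  enough to admit a 4-bead probe (docking recall target).
* ``make_ideal_helix`` — an ideal alpha-helix (rise 1.5 A, 100 deg/residue,
  radius 2.3 A).
* ``make_random_cluster`` — a compact globular blob with no special
  features (null model).

Same spec (kind, sizes, seed) -> byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .structure import Atom, Residue, Structure

__all__ = [
    "FixtureSpec",
    "make_hinge_dimer",
    "make_pocket_cluster",
    "make_ideal_helix",
    "make_random_cluster",
    "make_structure",
]

CA_SPACING = 3.8
#: every k-th residue is glycine (no CB) to exercise the Calpha fallback
GLY_PERIOD = 7


@dataclass
class FixtureSpec:
    kind: str                       # hinge_dimer | ideal_helix | pocket_cluster | random_cluster
    n_residues: int = 40
    seed: int = 0
    linker_len: int = 4
    pocket_depth: float = 11.0

    def to_dict(self) -> dict:
        return asdict(self)


def make_structure(spec: FixtureSpec) -> Structure:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "hinge_dimer":
        return make_hinge_dimer(n_per_domain=spec.n_residues,
                                linker_len=spec.linker_len, seed=spec.seed)
    if spec.kind == "ideal_helix":
        return make_ideal_helix(n=spec.n_residues)
    if spec.kind == "pocket_cluster":
        return make_pocket_cluster(n=spec.n_residues,
                                   pocket_depth=spec.pocket_depth,
                                   seed=spec.seed)
    if spec.kind == "random_cluster":
        return make_random_cluster(n=spec.n_residues, seed=spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# geometry helpers


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _normalize(np.cross(v, ref))


def _greedy_path(points: np.ndarray) -> np.ndarray:
    """Order lattice points into a chain by greedy nearest-neighbor walk,
    starting from the lexicographically smallest point."""
    pts = points.copy()
    order = [int(np.lexsort(pts.T[::-1])[0])]
    remaining = set(range(len(pts))) - {order[0]}
    while remaining:
        last = pts[order[-1]]
        rem = np.fromiter(remaining, dtype=int)
        d = np.linalg.norm(pts[rem] - last, axis=1)
        nxt = int(rem[np.argmin(d)])
        order.append(nxt)
        remaining.discard(nxt)
    return pts[order]


def _ball_lattice(n: int, rng: np.random.Generator,
                  carve=None, jitter: float = 0.2) -> np.ndarray:
    """Jittered cubic lattice points inside a ball, optionally carved by a
    predicate, ordered into a chain; exactly ``n`` points (closest to the
    center are kept)."""
    half = 1
    while True:
        ax = np.arange(-half, half + 1) * CA_SPACING
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        radius = half * CA_SPACING + 0.1
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        if carve is not None:
            pts = pts[~carve(pts)]
        if len(pts) >= n:
            break
        half += 1
    # keep the n points closest to the origin for compactness
    keep = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")[:n]
    pts = pts[np.sort(keep)]
    pts = _greedy_path(pts)
    return pts + rng.normal(0.0, jitter, size=pts.shape)


def _build_backbone(ca_path: np.ndarray, chain_id: str = "A",
                    first_seq: int = 1) -> list[Residue]:
    """Poly-ALA residues (GLY every GLY_PERIOD-th) around a Calpha path,
    with N/C/O/CB placed by ideal-ish local geometry."""
    n = len(ca_path)
    residues = []
    serial = 1
    for i in range(n):
        ca = ca_path[i]
        prev = ca_path[i - 1] if i > 0 else ca - (ca_path[i + 1] - ca)
        nxt = ca_path[i + 1] if i < n - 1 else ca + (ca - ca_path[i - 1])
        t = _normalize(nxt - prev)
        curv = (prev + nxt - 2.0 * ca)
        normal = curv - (curv @ t) * t
        normal = _normalize(normal) if np.linalg.norm(normal) > 1e-6 else _perpendicular(t)
        binorm = np.cross(t, normal)

        res_name = "GLY" if (i + 1) % GLY_PERIOD == 0 else "ALA"
        positions = {
            "N": ca - 1.46 * _normalize(t + 0.4 * normal),
            "CA": ca,
            "C": ca + 1.52 * _normalize(t - 0.4 * normal),
        }
        positions["O"] = positions["C"] + 1.23 * binorm
        if res_name != "GLY":
            positions["CB"] = ca + 1.53 * _normalize(-normal + binorm)
        atoms = []
        for name, pos in positions.items():
            atoms.append(Atom(serial=serial, name=name,
                              element="N" if name == "N" else ("O" if name == "O" else "C"),
                              coords=np.asarray(pos, dtype=float),
                              record_kind="polymer"))
            serial += 1
        residues.append(Residue(chain_id=chain_id, seq_number=first_seq + i,
                                insertion_code="", res_name=res_name,
                                atoms=atoms))
    return residues


# ---------------------------------------------------------------------------
# generators


def make_hinge_dimer(n_per_domain: int = 27, linker_len: int = 4,
                     seed: int = 0) -> Structure:
    """Two compact clusters joined by a thin linker across a 13.2 A cleft.

    The cleft width keeps the cluster faces beyond the default 12 A ENM
    cutoff (no direct cluster-cluster springs, so the hinge stays the
    softest internal motion) while still letting every linker residue
    anchor to both clusters, which keeps the framework rigid apart from
    the genuine hinge.  Metadata records the residue index ranges of the
    two clusters and the linker, and the cleft center."""
    if n_per_domain < 10:
        raise ValueError("n_per_domain must be >= 10")
    if linker_len < 3:
        raise ValueError(
            "linker_len must be >= 3: shorter linkers leave the two-cluster "
            "framework under-constrained (an exact internal mechanism)")
    rng = np.random.default_rng(seed)
    c1 = _ball_lattice(n_per_domain, rng)
    c2 = _ball_lattice(n_per_domain, rng)
    # Cleft width: cluster faces must exceed the 12 A ENM cutoff (no direct
    # cluster-cluster springs, keeping the hinge soft) while every linker
    # residue still anchors to both clusters.  A point node tethered to a
    # rigid body contributes at most 3 independent constraints however many
    # springs reach it, so linker nodes seeing only one cluster leave the
    # framework with an exact internal mechanism (a spurious 7th zero mode).
    gap = 13.2
    shift1 = -c1[:, 0].max()
    c1 = c1 + np.array([shift1, 0.0, 0.0])           # cluster 1 ends at x<=0
    c2 = c2 + np.array([gap - c2[:, 0].min(), 0.0, 0.0])  # starts at x>=gap
    # reorder so that the chain exits cluster 1 near x=0 and enters cluster 2
    # near x=gap: flip paths if needed
    if abs(c1[-1, 0]) > abs(c1[0, 0]):
        c1 = c1[::-1]
    if abs(c2[0, 0] - gap) > abs(c2[-1, 0] - gap):
        c2 = c2[::-1]
    start, end = c1[-1], c2[0]
    frac = np.arange(1, linker_len + 1)[:, None] / (linker_len + 1)
    linker = start + frac * (end - start)
    # non-planar arc: a collinear linker would leave torsion about the hinge
    # axis with no restoring force (a spurious 7th zero mode)
    arc = (1.2 * np.sin(np.pi * frac) * np.array([0.0, 1.0, 0.0])
           + 0.8 * np.sin(2.0 * np.pi * frac) * np.array([0.0, 0.0, 1.0]))
    linker = linker + arc + rng.normal(0.0, 0.05, size=linker.shape)
    path = np.concatenate([c1, linker, c2], axis=0)
    st = Structure(residues=_build_backbone(path),
                   source_label=f"hinge_dimer_n{n_per_domain}_l{linker_len}_s{seed}")
    n1 = n_per_domain
    st.metadata = {
        "kind": "hinge_dimer",
        "cluster1": [0, n1],
        "linker": [n1, n1 + linker_len],
        "cluster2": [n1 + linker_len, n1 + linker_len + n_per_domain],
        "cleft_center": list(0.5 * (start + end)),
        "seed": seed,
    }
    return st


def make_pocket_cluster(n: int = 36, pocket_depth: float = 10.4,
                        seed: int = 0) -> Structure:
    """Ring-stack cage with an open bore: a deep, fully concave pocket.

    Residues form stacked circular rings (~12 per ring, 3.8 A along each
    ring) whose common axis encloses a cylindrical bore of ~5 A free
    radius: wide enough for a 4-bead probe to enter from either mouth,
    narrow enough that a probe inside is rewarded by wall atoms on all
    sides.  ``pocket_depth`` is the bore length including the ~4 A reach
    of the rim atom clouds; it sets the ring spacing.  The recorded pocket
    center is the bore midpoint.  ``pocket_depth=0`` produces a convex
    solid-ball control with no cavity.

    The exposed outer wall is deliberately minimal (a short tube rather
    than a large globule): broad convex surfaces act as kinetic traps for
    surface probes, whereas here the bore is both the energetic optimum
    and the dominant capture target of the docking search."""
    if n < 30:
        raise ValueError("n must be >= 30")
    rng = np.random.default_rng(seed)
    if pocket_depth > 0:
        n_rings = max(3, n // 12)
        per_ring = n // n_rings
        radius = per_ring * CA_SPACING / (2.0 * np.pi)
        if not 5.7 <= radius <= 8.0:
            raise ValueError(
                f"n={n} gives ring radius {radius:.1f} A; the bore must "
                "have 5.7-8.0 A ring radius to admit a probe and still "
                "reward it (choose n so that n / max(3, n//12) is 10-13)")
        if pocket_depth < 4.0 + 2.5 * (n_rings - 1):
            raise ValueError("pocket_depth too small for the ring count")
        ring_gap = (pocket_depth - 4.0) / (n_rings - 1)
        if ring_gap > 4.2:
            raise ValueError("pocket_depth too large: rings would disconnect")
        pts = []
        for j in range(n_rings):
            z = (j - (n_rings - 1) / 2.0) * ring_gap
            phase = np.pi / per_ring * (j % 2)
            for i in range(per_ring):
                ang = 2.0 * np.pi * i / per_ring + phase
                if j % 2:
                    ang = -ang  # alternate winding so the chain zigzags
                pts.append([radius * np.cos(ang), radius * np.sin(ang), z])
        pts = np.array(pts) + rng.normal(0.0, 0.15, (len(pts), 3))
        center = [0.0, 0.0, 0.0]
    else:
        pts = _ball_lattice(n, rng)
        center = None
    st = Structure(residues=_build_backbone(pts),
                   source_label=f"pocket_n{n}_d{pocket_depth}_s{seed}")
    st.metadata = {"kind": "pocket_cluster", "pocket_center": center,
                   "pocket_depth": pocket_depth, "seed": seed}
    return st


def make_ideal_helix(n: int = 12) -> Structure:
    """Ideal alpha-helix Calpha trace: rise 1.5 A, 100 deg per residue,
    radius 2.3 A."""
    if n < 5:
        raise ValueError("n must be >= 5")
    theta = np.deg2rad(100.0) * np.arange(n)
    path = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                     1.5 * np.arange(n)], axis=1)
    st = Structure(residues=_build_backbone(path),
                   source_label=f"helix_n{n}")
    st.metadata = {"kind": "ideal_helix", "n": n}
    return st


def make_random_cluster(n: int = 40, seed: int = 0) -> Structure:
    """Compact featureless globular cluster (null model)."""
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    pts = _ball_lattice(n, rng)
    st = Structure(residues=_build_backbone(pts),
                   source_label=f"random_cluster_n{n}_s{seed}")
    st.metadata = {"kind": "random_cluster", "seed": seed}
    return st
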