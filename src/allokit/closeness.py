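"""Residue interaction graph (RIG) and degree-m local closeness.

The RIG has one node per polymer residue; an edge connects two residues
whenever any pair of their atoms (hydrogens included when present) is in
van der Waals contact, i.e. closer than the sum of the elemental vdW radii
plus a tolerance.  Local closeness of degree ``m`` is a truncated
harmonic centrality,

    LC_m(i) = sum_{k=1..m} n_k(i) / k,

where ``n_k(i)`` is the number of residues at shortest graph distance
exactly ``k`` from residue ``i``.  At ``m = 1`` it reduces to the node
degree; at the default ``m = 4`` only residues within roughly one domain
diameter (30-40 A) contribute, which is the regime where the measure best
highlights functional and regulatory binding sites.  Smaller ``m`` focuses
the measure on small surface cavities.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "VDW_RADII",
    "ResidueGraph",
    "ShellCounts",
    "build_rig",
    "shell_counts",
    "local_closeness_scores",
]

#: Elemental van der Waals radii (A); unknown elements fall back to carbon.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "D": 1.20, "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70


@dataclass
class ResidueGraph:
    graph: nx.Graph  # nodes are residue identity keys
    contact_tolerance: float

    @property
    def nodes(self):
        return self.graph.nodes

    def degree(self, node) -> int:
        return self.graph.degree[node]


@dataclass
class ShellCounts:
    node: tuple
    counts: list[int]  # n_1 .. n_m


def build_rig(s: Structure, tolerance: float = 0.5) -> ResidueGraph:
    """Build the residue interaction graph from van der Waals contacts.

    Edge (u, v) exists iff some atoms a in u, b in v satisfy
    dist(a, b) <= r_vdw(a) + r_vdw(b) + tolerance.
    """
    if len(s.residues) < 2:
        raise ValueError("need at least two polymer residues to build a RIG")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    coords, owner, radii = [], [], []
    for i, r in enumerate(s.residues):
        for a in r.atoms:
            coords.append(a.coords)
            owner.append(i)
            radii.append(VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS))
    coords = np.asarray(coords, dtype=float)
    owner = np.asarray(owner, dtype=int)
    radii = np.asarray(radii, dtype=float)

    g = nx.Graph()
    g.add_nodes_from(r.key for r in s.residues)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2.0 * radii.max() + tolerance, output_type="ndarray")
    if pairs.size:
        a, b = pairs[:, 0], pairs[:, 1]
        inter = owner[a] != owner[b]
        a, b = a[inter], b[inter]
        d = np.linalg.norm(coords[a] - coords[b], axis=1)
        touch = d <= radii[a] + radii[b] + tolerance
        edges = {tuple(sorted((owner[i], owner[j])))
                 for i, j in zip(a[touch], b[touch])}
        g.add_edges_from((s.residues[i].key, s.residues[j].key)
                         for i, j in edges)
    return ResidueGraph(graph=g, contact_tolerance=tolerance)


def shell_counts(g: ResidueGraph, node, m: int) -> ShellCounts:
    """Count nodes at shortest distance exactly k (k = 1..m) from ``node``
    by breadth-first search truncated at depth m."""
    if node not in g.graph:
        raise ValueError(f"unknown node {node!r}")
    if m < 1:
        raise ValueError("m must be >= 1")
    dist = nx.single_source_shortest_path_length(g.graph, node, cutoff=m)
    counts = [0] * m
    for d in dist.values():
        if 1 <= d <= m:
            counts[d - 1] += 1
    return ShellCounts(node=node, counts=counts)


def local_closeness_scores(g: ResidueGraph, m: int = 4) -> dict:
    """Degree-m local closeness for every node: sum_k n_k / k."""
    if g.graph.number_of_nodes() == 0:
        raise ValueError("empty residue interaction graph")
    if m < 1:
        raise ValueError("m must be >= 1")
    scores = {}
    for node in g.graph.nodes:
        sc = shell_counts(g, node, m)
        scores[node] = float(sum(n / k for k, n in enumerate(sc.counts, start=1)))
    return scores
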