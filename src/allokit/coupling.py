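"""Leverage coupling: quantifying allosteric communication between sites.

Each site P gets a per-mode leverage vector lambda_P, whose component for
mode mu is the spring deformation energy DeltaU_mu of the site's spring
set divided by the number of elements in the set (size normalization).
The communication strength between two sites is the dot product

    D_PQ = lambda_P . lambda_Q  >= 0,

large when both sites exert leverage on the same collective motions.  The
normalized coupling C_PQ = D_PQ / sqrt(D_PP * D_QQ) is the cosine between
the leverage vectors and lies in [0, 1] (the components are non-negative);
it makes values comparable across sites of very different size, as needed
for large molecular machines.  A background pseudo-site (BG) of all
residues not in any annotated site provides a control coupling level and
occupies the last row/column of the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enm import ModeSet
from .leverage import SPRING_SHELL, binding_leverage_score, select_springs
from .structure import Site, Structure, background_site, _with_pseudo_ligand

__all__ = [
    "LeverageVector",
    "CouplingMatrix",
    "site_lambda",
    "coupling_matrix",
    "normalize_coupling",
    "display_transform",
    "site_vs_structure",
]

logger = logging.getLogger(__name__)


@dataclass
class LeverageVector:
    site_id: str
    components: np.ndarray   # lambda_P^mu >= 0, one per retained mode
    n_elements: int          # set size used for normalization


@dataclass
class CouplingMatrix:
    site_ids: list[str]      # ordered; background "BG" last when present
    values: np.ndarray       # symmetric (S, S)
    kind: str                # "D" | "C" | "display"
    zero_sites: list[str] | None = None  # sites with vanishing leverage


def site_lambda(site: Site, s: Structure, modes: ModeSet,
                shell: float = SPRING_SHELL,
                norm: str = "springs") -> LeverageVector:
    """Per-mode leverage vector of a site.

    Springs are selected around the site's probe atoms (ligand atoms,
    docked beads, or the side-chain pseudo-ligand) with the usual shell;
    each component is DeltaU_mu divided by the set size: the number of
    springs (default) or, alternatively, the number of site residues
    (``norm="residues"``).  A site producing no springs yields a zero
    vector (logged)."""
    if site.probe_atoms is None or np.size(site.probe_atoms) == 0:
        if site.origin == "background" and not site.residue_keys:
            return LeverageVector(site.site_id,
                                  np.zeros(modes.n_modes), 0)
        raise ValueError(f"site {site.site_id!r} has no probe atoms")
    if norm not in ("springs", "residues"):
        raise ValueError("norm must be 'springs' or 'residues'")
    ca = s.ca_coords()
    springs = select_springs(ca, site.probe_atoms, shell=shell,
                             source=site.site_id)
    if len(springs) == 0:
        logger.warning("site %s selected no springs; leverage vector is zero",
                       site.site_id)
        return LeverageVector(site.site_id, np.zeros(modes.n_modes), 0)
    res = binding_leverage_score(springs, modes)
    n = len(springs) if norm == "springs" else max(len(site.residue_keys), 1)
    return LeverageVector(site.site_id, res.per_mode / n, n)


def coupling_matrix(sites: Sequence[Site], s: Structure, modes: ModeSet,
                    include_background: bool = True,
                    shell: float = SPRING_SHELL,
                    norm: str = "springs") -> CouplingMatrix:
    """Symmetric site-by-site matrix of D_PQ = lambda_P . lambda_Q.

    With ``include_background`` a BG pseudo-site built from all residues
    not covered by ``sites`` is appended as the last row/column."""
    all_sites = list(sites)
    if include_background:
        all_sites.append(background_site(s, sites))
    if len(all_sites) < 2:
        raise ValueError("need at least two sites (or one site plus background)")
    lams = [site_lambda(t, s, modes, shell=shell, norm=norm)
            for t in all_sites]
    lam = np.array([v.components for v in lams])        # (S, K)
    d = lam @ lam.T
    d = 0.5 * (d + d.T)  # exact symmetry
    zero = [v.site_id for v in lams if not np.any(v.components)]
    return CouplingMatrix(site_ids=[t.site_id for t in all_sites],
                          values=d, kind="D", zero_sites=zero)


def normalize_coupling(dmat: CouplingMatrix) -> CouplingMatrix:
    """Cosine-normalized coupling C_PQ = D_PQ / sqrt(D_PP D_QQ), in [0, 1].

    Sites with zero self-coupling get zero rows/columns (flagged in
    ``zero_sites``); the diagonal is exactly 1 where D_PP > 0."""
    if dmat.kind != "D":
        raise ValueError("normalize_coupling expects a raw D matrix")
    d = dmat.values
    diag = np.diag(d).copy()
    denom = np.sqrt(np.outer(diag, diag))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    if c.size and np.nanmax(c) > 1.0 + 1e-9:
        raise FloatingPointError("normalized coupling exceeded 1 beyond rounding")
    c = np.clip(c, 0.0, 1.0)
    np.fill_diagonal(c, np.where(diag > 0, 1.0, 0.0))
    zero = [sid for sid, v in zip(dmat.site_ids, diag) if v == 0]
    return CouplingMatrix(site_ids=list(dmat.site_ids), values=c, kind="C",
                          zero_sites=zero)


def display_transform(dmat: CouplingMatrix,
                      subtract_background: bool = False) -> CouplingMatrix:
    """Display normalization: values scaled to [0, 1] by the maximal
    off-diagonal entry, optionally after subtracting the mean background
    coupling of each pair (clamped at zero)."""
    if dmat.kind != "D":
        raise ValueError("display_transform expects a raw D matrix")
    v = dmat.values.copy()
    if subtract_background:
        if not dmat.site_ids or dmat.site_ids[-1] != "BG":
            raise ValueError("background subtraction needs a BG row/column (last)")
        bg = v[:, -1]
        v = np.maximum(0.0, v - 0.5 * (bg[:, None] + bg[None, :]))
    off = v[~np.eye(len(v), dtype=bool)] if len(v) > 1 else np.array([])
    peak = float(off.max()) if off.size else 0.0
    if peak <= 0:
        logger.warning("all couplings are zero; display matrix is all zeros")
        out = np.zeros_like(v)
    else:
        out = np.clip(v / peak, 0.0, None)
    return CouplingMatrix(site_ids=list(dmat.site_ids), values=out,
                          kind="display", zero_sites=dmat.zero_sites)


def site_vs_structure(site: Site, s: Structure, modes: ModeSet,
                      shell: float = SPRING_SHELL,
                      norm: str = "springs") -> dict:
    """Communication between one site and every residue of the structure.

    Residues outside the site get D(lambda_site, lambda_r) where lambda_r
    is the leverage vector of the single-residue pseudo-site at r; the
    site's own residues carry the site self-coupling."""
    lam_site = site_lambda(site, s, modes, shell=shell, norm=norm).components
    self_coupling = float(lam_site @ lam_site)
    values: dict = {}
    for r in s.residues:
        if r.key in site.residue_keys:
            values[r.key] = self_coupling
            continue
        pseudo = _with_pseudo_ligand(s, {r.key}, site_id=f"res:{r.key}",
                                     origin="user_list")
        lam_r = site_lambda(pseudo, s, modes, shell=shell, norm=norm).components
        values[r.key] = float(lam_site @ lam_r)
    return values
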