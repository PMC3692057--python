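"""Protein structure model: parsing, chain selection, site definition, B-factor output.

A :class:`Structure` is the single source of geometry for the whole package.
It holds an ordered list of polymer residues plus the non-solvent HETATM
groups (:class:`LigandGroup`) found in the file.  Binding sites — whether
extracted from bound ligands, defined by the user, or produced by probe
docking — are represented uniformly as :class:`Site` objects carrying the
"probe atoms" (ligand atoms, docked beads, or side-chain pseudo-ligand
atoms) that downstream spring selection operates on.

All coordinates are in Angstroms; residue numbering follows the input file
verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "LigandGroup",
    "Site",
    "Structure",
    "StructureError",
    "DEFAULT_EXCLUDED_RESNAMES",
    "read_pdb",
    "select_chains",
    "sites_from_ligands",
    "site_from_sphere",
    "site_from_residues",
    "site_from_pose",
    "background_site",
    "parse_key",
    "write_bfactor_pdb",
]

#: HETATM residue names never treated as ligands (solvent, common ions,
#: cryoprotectants).  Configurable via ``read_pdb(exclude=...)``.
DEFAULT_EXCLUDED_RESNAMES = frozenset(
    {"HOH", "DOD", "NA", "K", "CL", "MG", "ZN", "CA", "SO4", "PO4", "GOL", "EDO"}
)

#: Backbone atom names; everything else heavy counts as side chain.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structural input."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    record_kind: str  # "polymer" | "hetero"
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity key, unique within a Structure."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA" and a.element == "C":
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)

    def sidechain_pseudo_ligand(self) -> np.ndarray:
        """Heavy side-chain atom coordinates; falls back to Calpha (glycine)."""
        side = [a.coords for a in self.atoms
                if a.is_heavy and a.name not in BACKBONE_ATOM_NAMES]
        if side:
            return np.array(side, dtype=float)
        ca = self.ca
        if ca is not None:
            return ca.coords[None, :].astype(float)
        return self.heavy_coords()


@dataclass
class LigandGroup:
    group_id: str
    res_name: str
    atoms: list[Atom]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class Site:
    site_id: str
    residue_keys: set[tuple[str, int, str]]
    origin: str  # ligand | user_sphere | user_list | docked | background
    probe_atoms: np.ndarray | None = None  # (P, 3) coordinates defining the site


@dataclass
class Structure:
    residues: list[Residue]
    ligand_groups: list[LigandGroup] = field(default_factory=list)
    source_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {r.key: i for i, r in enumerate(self.residues)}
        if len(self._index) != len(self.residues):
            raise StructureError("duplicate residue identity keys")

    def residue(self, key: tuple[str, int, str]) -> Residue:
        try:
            return self.residues[self._index[key]]
        except KeyError:
            raise StructureError(f"unknown residue key {key!r}") from None

    def residue_position(self, key: tuple[str, int, str]) -> int:
        return self._index[key]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def ca_coords(self) -> np.ndarray:
        """One Calpha coordinate per polymer residue, in residue order."""
        coords = []
        for r in self.residues:
            ca = r.ca
            if ca is None:
                raise StructureError(
                    f"residue {r.key} has no Calpha; cannot build an elastic network"
                )
            coords.append(ca.coords)
        return np.array(coords, dtype=float)

    def heavy_atom_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All polymer heavy-atom coordinates and their residue indices."""
        coords, owner = [], []
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                if a.is_heavy:
                    coords.append(a.coords)
                    owner.append(i)
        return np.array(coords, dtype=float), np.array(owner, dtype=int)


def _infer_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _convert_residue(chain_id: str, res: "gemmi.Residue", kind: str) -> Residue:
    # altloc resolution: keep, per atom name, the highest-occupancy conformer
    # (ties: first encountered).
    chosen: dict[str, "gemmi.Atom"] = {}
    for a in res:
        prev = chosen.get(a.name)
        if prev is None or a.occ > prev.occ:
            chosen[a.name] = a
    atoms = []
    for a in chosen.values():
        elem = a.element.name.strip().upper()
        if not elem or elem == "X":
            elem = _infer_element(a.name)
        atoms.append(
            Atom(
                serial=a.serial,
                name=a.name,
                element=elem,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                record_kind=kind,
                occupancy=a.occ,
                bfactor=a.b_iso,
            )
        )
    return Residue(
        chain_id=chain_id,
        seq_number=res.seqid.num,
        insertion_code=(res.seqid.icode or " ").strip(),
        res_name=res.name.strip(),
        atoms=atoms,
    )


def read_pdb(path: str | Path,
             exclude: Iterable[str] = DEFAULT_EXCLUDED_RESNAMES) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first MODEL is used; alternate locations are resolved to the
    highest-occupancy conformer.  HETATM residues whose name is not on the
    exclusion list become :class:`LigandGroup` objects, grouped by
    (chain, residue name, sequence number).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    excluded = {name.upper() for name in exclude}

    model = st[0]
    residues: list[Residue] = []
    ligands: list[LigandGroup] = []
    seen_keys: set[tuple[str, int, str]] = set()
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            if is_het:
                if res.name.strip().upper() in excluded:
                    continue
                conv = _convert_residue(chain.name, res, "hetero")
                gid = f"{conv.res_name}_{chain.name}{conv.seq_number}{conv.insertion_code}"
                ligands.append(LigandGroup(group_id=gid, res_name=conv.res_name,
                                           atoms=conv.atoms))
            else:
                conv = _convert_residue(chain.name, res, "polymer")
                if conv.key in seen_keys:
                    continue  # microheterogeneity: first record wins
                seen_keys.add(conv.key)
                residues.append(conv)
    if not residues:
        raise StructureError(f"{path} contains no polymer residues")
    residues.sort(key=lambda r: (r.chain_id, r.seq_number, r.insertion_code))
    return Structure(residues=residues, ligand_groups=ligands,
                     source_label=path.stem)


def select_chains(s: Structure, chain_ids: Iterable[str]) -> Structure:
    """Restrict a structure to the named chains, preserving order."""
    wanted = set(chain_ids)
    present = set(s.chain_ids)
    unknown = wanted - present
    if unknown:
        raise StructureError(
            f"unknown chain id(s) {sorted(unknown)}; valid chains: {sorted(present)}"
        )
    residues = [r for r in s.residues if r.chain_id in wanted]
    ligands = [g for g in s.ligand_groups
               if g.atoms and _ligand_chain(g) in wanted]
    return Structure(residues=residues, ligand_groups=ligands,
                     source_label=s.source_label, metadata=dict(s.metadata))


def _ligand_chain(g: LigandGroup) -> str:
    # group_id is "<resname>_<chain><seq>"; recover the chain from the tail
    tail = g.group_id.split("_", 1)[1]
    for i, ch in enumerate(tail):
        if ch.isdigit() or ch == "-":
            return tail[:i]
    return tail


def sites_from_ligands(s: Structure, contact_cutoff: float = 4.5) -> list[Site]:
    """One site per ligand group: residues with a heavy atom within
    ``contact_cutoff`` of any ligand heavy atom.  Groups contacting no
    residue are dropped."""
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    coords, owner = s.heavy_atom_table()
    sites: list[Site] = []
    for g in s.ligand_groups:
        lig = g.heavy_coords()
        if lig.size == 0:
            continue
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        hit = np.unique(owner[(d2 <= contact_cutoff**2).any(axis=1)])
        if hit.size == 0:
            continue
        keys = {s.residues[i].key for i in hit}
        sites.append(Site(site_id=g.group_id, residue_keys=keys,
                          origin="ligand", probe_atoms=lig))
    return sites


def site_from_sphere(s: Structure, center_key: tuple[str, int, str],
                     radius: float = 6.0, site_id: str | None = None) -> Site:
    """User site: every residue with a heavy atom within ``radius`` of any
    heavy atom of the center residue (center included)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = s.residue(center_key)
    ref = center.heavy_coords()
    coords, owner = s.heavy_atom_table()
    d2 = ((coords[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    hit = np.unique(owner[(d2 <= radius**2).any(axis=1)])
    keys = {s.residues[i].key for i in hit}
    keys.add(center_key)
    return _with_pseudo_ligand(
        s, keys, site_id or _key_str(center_key), origin="user_sphere")


def site_from_residues(s: Structure, keys: Iterable[tuple[str, int, str]],
                       site_id: str) -> Site:
    """User site from an explicit residue list."""
    keyset = set(keys)
    for k in keyset:
        s.residue(k)  # raises on unknown keys
    if not keyset:
        raise StructureError("a user site needs at least one residue")
    return _with_pseudo_ligand(s, keyset, site_id, origin="user_list")


def site_from_pose(s: Structure, beads: np.ndarray, site_id: str,
                   cutoff: float = 4.5) -> Site:
    """Site induced by docked probe beads: residues with a heavy atom
    within ``cutoff`` of any bead."""
    coords, owner = s.heavy_atom_table()
    beads = np.asarray(beads, dtype=float)
    d2 = ((coords[:, None, :] - beads[None, :, :]) ** 2).sum(axis=2)
    hit = np.unique(owner[(d2 <= cutoff**2).any(axis=1)])
    keys = {s.residues[i].key for i in hit}
    return Site(site_id=site_id, residue_keys=keys, origin="docked",
                probe_atoms=beads)


def _with_pseudo_ligand(s: Structure, keys: set, site_id: str, origin: str) -> Site:
    """Residue-defined sites get side-chain heavy atoms (Calpha for glycine)
    as pseudo-ligand probe atoms so spring selection applies uniformly."""
    blocks = [s.residue(k).sidechain_pseudo_ligand() for k in sorted(keys)]
    blocks = [b for b in blocks if b.size]
    probe = np.concatenate(blocks, axis=0) if blocks else np.empty((0, 3))
    return Site(site_id=site_id, residue_keys=keys, origin=origin,
                probe_atoms=probe)


def background_site(s: Structure, sites: Sequence[Site],
                    site_id: str = "BG") -> Site:
    """Pseudo-site of all residues not included in any given site."""
    covered: set = set()
    for site in sites:
        covered |= site.residue_keys
    keys = {r.key for r in s.residues} - covered
    if not keys:
        return Site(site_id=site_id, residue_keys=set(), origin="background",
                    probe_atoms=np.empty((0, 3)))
    site = _with_pseudo_ligand(s, keys, site_id, origin="background")
    return site


def _key_str(key: tuple[str, int, str]) -> str:
    chain, seq, icode = key
    return f"{chain}:{seq}{icode}"


def parse_key(text: str) -> tuple[str, int, str]:
    """Parse "A:42" or "A:42B" into a residue identity key."""
    chain, _, rest = text.partition(":")
    if not rest:
        raise StructureError(f"cannot parse residue key {text!r} (want CHAIN:SEQ)")
    num = rest
    icode = ""
    if rest and rest[-1].isalpha():
        num, icode = rest[:-1], rest[-1]
    return (chain, int(num), icode)


def write_bfactor_pdb(s: Structure, values: Mapping[tuple[str, int, str], float],
                      path: str | Path) -> None:
    """Write the structure as PDB with per-residue values in the B-factor
    column (fixed 6.2 formatting; residues absent from the map carry 0.00)."""
    for key, v in values.items():
        s.residue(key)
        if not math.isfinite(v):
            raise StructureError(f"non-finite B-factor value for residue {key}")
    st = gemmi.Structure()
    st.name = s.source_label or "allokit"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def _chain(cid: str) -> gemmi.Chain:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        return chains[cid]

    def _emit(chain_id: str, res_like, het: bool, b: float) -> None:
        gres = gemmi.Residue()
        gres.name = res_like.res_name
        gres.seqid = gemmi.SeqId(res_like.seq_number,
                                 getattr(res_like, "insertion_code", "") or " ")
        gres.het_flag = "H" if het else "A"
        for a in res_like.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.b_iso = b
            gres.add_atom(ga)
        _chain(chain_id).add_residue(gres)

    for r in s.residues:
        _emit(r.chain_id, r, het=False, b=float(values.get(r.key, 0.0)))
    for g in s.ligand_groups:
        fake = Residue(chain_id=_ligand_chain(g),
                       seq_number=g.atoms[0].serial if g.atoms else 0,
                       insertion_code="", res_name=g.res_name, atoms=g.atoms)
        # ligand groups keep their original numbering via the group id tail
        tail = g.group_id.split("_", 1)[1][len(_ligand_chain(g)):]
        num = "".join(ch for ch in tail if ch.isdigit() or ch == "-")
        fake.seq_number = int(num) if num else 0
        _emit(fake.chain_id, fake, het=True, b=0.0)

    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path), gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))
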