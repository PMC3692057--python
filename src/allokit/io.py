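"""Plain-text output formats: per-residue tables, coupling matrices,
serialized mode sets and probe poses.

All writers are deterministic: fixed float formatting, sorted keys, no
timestamps — rerunning a pipeline with the same seed reproduces the files
byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coupling import CouplingMatrix
from .enm import ModeSet
from .leverage import ProbePose
from .structure import Structure

__all__ = [
    "write_residue_table",
    "write_matrix_json",
    "read_matrix_json",
    "write_modes_json",
    "read_modes_json",
    "write_poses_pdb",
]


def write_residue_table(s: Structure, values: Mapping, path: str | Path,
                        column: str = "score") -> pd.DataFrame:
    """Tab-separated per-residue table: chain, seq_number, insertion_code,
    res_name, <column>."""
    rows = [
        {
            "chain": r.chain_id,
            "seq_number": r.seq_number,
            "insertion_code": r.insertion_code,
            "res_name": r.res_name,
            column: float(values.get(r.key, 0.0)),
        }
        for r in s.residues
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df


def write_matrix_json(m: CouplingMatrix, path: str | Path) -> None:
    payload = {
        "sites": list(m.site_ids),
        "kind": m.kind,
        "values": [[float(v) for v in row] for row in m.values],
    }
    if m.zero_sites:
        payload["zero_leverage_sites"] = list(m.zero_sites)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_matrix_json(path: str | Path) -> CouplingMatrix:
    payload = json.loads(Path(path).read_text())
    return CouplingMatrix(site_ids=list(payload["sites"]),
                          values=np.array(payload["values"], dtype=float),
                          kind=payload["kind"],
                          zero_sites=payload.get("zero_leverage_sites"))


def write_modes_json(modes: ModeSet, path: str | Path) -> None:
    payload = {
        "eigenvalues": [float(v) for v in modes.eigenvalues],
        "eigenvectors": [[float(x) for x in modes.eigenvectors[:, k]]
                         for k in range(modes.n_modes)],
        "n_zero": modes.n_zero,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_modes_json(path: str | Path) -> ModeSet:
    payload = json.loads(Path(path).read_text())
    vecs = np.array(payload["eigenvectors"], dtype=float).T
    return ModeSet(eigenvalues=np.array(payload["eigenvalues"], dtype=float),
                   eigenvectors=vecs, n_zero=int(payload["n_zero"]))


def write_poses_pdb(poses: list[ProbePose], path: str | Path) -> None:
    """Probe poses as a multi-MODEL PDB of pseudo-Calpha beads."""
    lines = []
    for k, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {k:4d}")
        for b, xyz in enumerate(pose.beads, start=1):
            lines.append(
                f"ATOM  {b:5d}  CA  PRB A{b:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{pose.energy:6.2f}           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
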