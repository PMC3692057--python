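import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allokit import fixtures as fx
from allokit.enm import build_elastic_network, compute_modes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix():
    return fx.make_ideal_helix(12)


@pytest.fixture(scope="session")
def hinge():
    return fx.make_hinge_dimer(27, 4, seed=1)


@pytest.fixture(scope="session")
def hinge_modes(hinge):
    return compute_modes(build_elastic_network(hinge, 12.0), 10)


@pytest.fixture(scope="session")
def pocket():
    return fx.make_pocket_cluster()


@pytest.fixture(scope="session")
def blob():
    return fx.make_random_cluster(40, seed=3)


@pytest.fixture(scope="session")
def blob_modes(blob):
    return compute_modes(build_elastic_network(blob, 12.0), 10)


def rotate_structure(s, rot, shift=None):
    """Deep-copied structure with every atom coordinate rigidly moved."""
    from dataclasses import replace

    from allokit.structure import LigandGroup, Residue, Structure

    shift = np.zeros(3) if shift is None else np.asarray(shift)

    def move(atoms):
        return [replace(a, coords=rot @ a.coords + shift) for a in atoms]

    residues = [Residue(r.chain_id, r.seq_number, r.insertion_code,
                        r.res_name, move(r.atoms)) for r in s.residues]
    ligands = [LigandGroup(g.group_id, g.res_name, move(g.atoms))
               for g in s.ligand_groups]
    return Structure(residues=residues, ligand_groups=ligands,
                     source_label=s.source_label, metadata=dict(s.metadata))


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
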