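import numpy as np
import pandas as pd
import pytest

from pepsurf.model import Residue, Topology
from pepsurf.synthetic import Trajectory, generate_trajectory, preset


def toy_topology(z_atoms, masses=None, resids=None, element="C"):
    """Minimal topology for geometric tests: one named atom per entry."""
    n = len(z_atoms)
    masses = [1.0] * n if masses is None else masses
    resids = list(range(1, n + 1)) if resids is None else resids
    atoms = pd.DataFrame(
        dict(
            name=["CA"] * n,
            element=[element] * n,
            resid=resids,
            role=["backbone"] * n,
            donor=[False] * n,
            acceptor=[False] * n,
            charge=[0.0] * n,
            sigma=[3.5] * n,
            epsilon=[0.1] * n,
            mass=masses,
        )
    )
    residues = [Residue(r, "G") for r in sorted(set(resids))]
    return Topology(residues=residues, atoms=atoms)


@pytest.fixture(scope="session")
def samch3():
    """Hydrophobic-surface scenario: 5000 frames, two designed helices,
    permanently adsorbed."""
    return generate_trajectory(preset("samch3-like", seed=11))


@pytest.fixture(scope="session")
def samoh():
    """Transient-adsorption scenario: 5000 frames of two-state kinetics."""
    return generate_trajectory(preset("samoh-like", seed=12))


@pytest.fixture(scope="session")
def planted_contacts():
    """Desorbed baseline with Bernoulli-planted residue contacts, so the
    contact analysis has an exact binomial ground truth."""
    spec = preset(
        "samoh-like",
        k_ads=0.0, k_des=0.0, start_adsorbed=False, seed=13,
        planted_contacts={12: 0.3, 17: 0.7, 24: 0.5},
    )
    return generate_trajectory(spec)


def make_trajectory(z_atoms, z0=0.0, ligand="CH3", n_frames=1, masses=None, resids=None):
    """Trajectory of static atoms at given heights above a flat surface."""
    from pepsurf.model import build_sam_surface

    topo = toy_topology(z_atoms, masses=masses, resids=resids)
    surface = build_sam_surface(4, 4, ligand, chain_height=10.0)
    coords = np.zeros((n_frames, len(z_atoms), 3))
    center = surface.chain_positions.mean(axis=0)
    coords[:, :, 0] = center[0] + np.arange(len(z_atoms)) * 0.1
    coords[:, :, 1] = center[1]
    coords[:, :, 2] = surface.z0 + np.asarray(z_atoms)
    return Trajectory(topology=topo, frames=coords, surface=surface)
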